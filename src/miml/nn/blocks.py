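"""Residual block: two 3x3 convs with an additive shortcut.

The shortcut is the identity when shape is preserved; a 1x1 strided
convolution (plus batch norm) projects it when the block downsamples or
changes width.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Layer, Param, ReLU, Sequential


class ResidualBlock(Layer):
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.main = Sequential(
            [
                ("conv1", Conv2d(c_in, c_out, 3, rng, stride=stride)),
                ("bn1", BatchNorm2d(c_out)),
                ("relu1", ReLU()),
                ("conv2", Conv2d(c_out, c_out, 3, rng, stride=1)),
                ("bn2", BatchNorm2d(c_out)),
            ]
        )
        if stride != 1 or c_in != c_out:
            self.shortcut: Layer = Sequential(
                [
                    ("conv", Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0)),
                    ("bn", BatchNorm2d(c_out)),
                ]
            )
            self.projects = True
        else:
            self.shortcut = None  # identity
            self.projects = False
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        branch = self.main.forward(x, train=train)
        skip = self.shortcut.forward(x, train=train) if self.projects else x
        if branch.shape != skip.shape:  # pragma: no cover - guarded by construction
            raise ValueError(
                f"residual operand shapes differ: {branch.shape} vs {skip.shape}"
            )
        return self.relu_out.forward(branch + skip, train=train)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dx = self.main.backward(dsum)
        if self.projects:
            dx = dx + self.shortcut.backward(dsum)
        else:
            dx = dx + dsum
        return dx

    def parameters(self):
        out = {f"main.{k}": p for k, p in self.main.parameters().items()}
        if self.projects:
            out.update({f"shortcut.{k}": p for k, p in self.shortcut.parameters().items()})
        return out

    def buffers(self):
        out = {f"main.{k}": v for k, v in self.main.buffers().items()}
        if self.projects:
            out.update({f"shortcut.{k}": v for k, v in self.shortcut.buffers().items()})
        return out

    def load_buffers(self, buffers):
        main = {k[5:]: v for k, v in buffers.items() if k.startswith("main.")}
        self.main.load_buffers(main)
        if self.projects:
            sc = {k[9:]: v for k, v in buffers.items() if k.startswith("shortcut.")}
            self.shortcut.load_buffers(sc)
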