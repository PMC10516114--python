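"""Residual convolutional image encoder and its image-only classifier.

Architecture: a 7x7 stride-2 stem convolution with batch norm, ReLU and max
pooling, followed by ``stages`` stages of residual blocks. Filters start at
``base_filters`` and double at every stage; stages 2..N downsample with
stride 2 in their first block, where a 1x1 projection convolution matches the
shortcut dimensions. A global average pool produces the embedding; a final
fully connected layer (head='classifier') or the identity (head='identity')
sits on top.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig",
    "Encoder",
    "build_encoder",
    "encode",
    "train_image_classifier",
    "TrainHistory",
    "LeakageError",
]


class LeakageError(ValueError):
    """Same cell appears in more than one split."""


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 1
    base_filters: int = 64
    stages: int = 4
    blocks_per_stage: int = 2
    image_size: tuple[int, int] = (64, 64)
    head: str = "classifier"  # or "identity"
    n_classes: int = 2

    def __post_init__(self):
        if self.head not in ("classifier", "identity"):
            raise ValueError(f"head must be 'classifier' or 'identity', got {self.head!r}")
        if self.stages < 1 or self.blocks_per_stage < 1 or self.base_filters < 1:
            raise ValueError("stages, blocks_per_stage and base_filters must be >= 1")
        h, w = self.image_size
        # stem conv (s2) + stem pool (s2) + stride-2 first blocks of stages 2..N
        reductions = 2 + (self.stages - 1)
        if min(h, w) < 2**reductions:
            raise ValueError(
                f"image {h}x{w} too small to survive {reductions} stride-2 "
                f"reductions; need at least {2**reductions} px per side"
            )

    @property
    def stage_filters(self) -> list[int]:
        return [self.base_filters * 2**k for k in range(self.stages)]

    @property
    def embedding_width(self) -> int:
        return self.base_filters * 2 ** (self.stages - 1)


class Encoder:
    """Encoder + optional classification head, with manual backprop."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[tuple[str, nn.Layer]] = [
            ("stem_conv", nn.Conv2d(config.in_channels, config.base_filters, 7, rng, stride=2, pad=3)),
            ("stem_bn", nn.BatchNorm2d(config.base_filters)),
            ("stem_relu", nn.ReLU()),
            ("stem_pool", nn.MaxPool2d()),
        ]
        c_in = config.base_filters
        for k, c_out in enumerate(config.stage_filters, start=1):
            blocks: list[tuple[str, nn.Layer]] = []
            for bi in range(config.blocks_per_stage):
                stride = 2 if (k > 1 and bi == 0) else 1
                blocks.append((f"block{bi + 1}", nn.ResidualBlock(c_in, c_out, stride, rng)))
                c_in = c_out
            layers.append((f"stage{k}", nn.Sequential(blocks)))
        layers.append(("gap", nn.GlobalAvgPool2d()))
        self.net = nn.Sequential(layers)
        if config.head == "classifier":
            self.fc: nn.Layer = nn.Linear(config.embedding_width, config.n_classes, rng)
        else:
            self.fc = nn.Identity()

    # -- forward/backward -------------------------------------------------
    def embed(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Embeddings (N, embedding_width); the head is not applied."""
        self._check_batch(images)
        return self.net.forward(images, train=train)

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (classifier head) or embeddings (identity head)."""
        z = self.embed(images, train=train)
        return self.fc.forward(z, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(self.fc.backward(dlogits))

    def _check_batch(self, images: np.ndarray) -> None:
        if images.ndim != 4 or images.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected batch of shape (N, {self.config.in_channels}, H, W), "
                f"got {images.shape}"
            )

    # -- parameter access -------------------------------------------------
    def parameters(self) -> dict[str, nn.Param]:
        out = {f"net.{k}": p for k, p in self.net.parameters().items()}
        out.update({f"fc.{k}": p for k, p in self.fc.parameters().items()})
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.value.copy() for k, p in self.parameters().items()}
        out.update({f"buf.net.{k}": v.copy() for k, v in self.net.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, p in params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k}")
            if state[k].shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {state[k].shape} vs model {p.value.shape}"
                )
            p.value[...] = state[k]
        bufs = {k[8:]: v for k, v in state.items() if k.startswith("buf.net.")}
        self.net.load_buffers(bufs)

    def stage_output_layer(self, which: str) -> str:
        """Resolve Grad-CAM layer names to encoder stages."""
        names = {"last": f"stage{self.config.stages}", "penultimate": f"stage{self.config.stages - 1}"}
        if which in names:
            return names[which]
        available = [n for n, _ in self.net.layers]
        if which in available:
            return which
        raise KeyError(f"unknown layer {which!r}; available: {['last', 'penultimate'] + available}")


def build_encoder(config: EncoderConfig, seed: int = 0) -> Encoder:
    """Construct the encoder; raises at build time on invalid shapes."""
    return Encoder(config, seed=seed)


def encode(encoder: Encoder, images: np.ndarray) -> np.ndarray:
    """Eval-mode embeddings; requires head='identity'."""
    if encoder.config.head != "identity":
        raise ValueError("encode() requires an encoder built with head='identity'")
    return encoder.forward(images, train=False)


@dataclass
class TrainHistory:
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0


def _accuracy(model, images, labels, batch_size=128, cap=None) -> float:
    if cap is not None and len(labels) > cap:
        images, labels = images[:cap], labels[:cap]
    correct = 0
    for lo in range(0, len(labels), batch_size):
        logits = model.forward(images[lo : lo + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == labels[lo : lo + batch_size]).sum())
    return correct / len(labels)


def check_disjoint_cells(train_ids, val_ids) -> None:
    shared = set(train_ids) & set(val_ids)
    if shared:
        raise LeakageError(f"cells present in both splits: {sorted(shared)[:5]} ...")


def train_image_classifier(
    encoder: Encoder,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    train_cell_ids=None,
    val_cell_ids=None,
    epochs: int = 40,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> TrainHistory:
    """Train the classifier head end to end; keeps the best-val-epoch weights.

    Raises :class:`LeakageError` if any cell id occurs in both splits.
    """
    if encoder.config.head != "classifier":
        raise ValueError("training requires head='classifier'")
    if train_cell_ids is not None and val_cell_ids is not None:
        check_disjoint_cells(train_cell_ids, val_cell_ids)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(encoder.parameters(), lr=lr)
    history = TrainHistory()
    best_state = encoder.state_dict()
    n = len(train_labels)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            if len(idx) < 2:  # batch norm needs at least 2 samples
                continue
            logits = encoder.forward(train_images[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, train_labels[idx])
            opt.zero_grad()
            encoder.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        # train accuracy estimated on a capped prefix to bound eval cost
        history.train_acc.append(_accuracy(encoder, train_images, train_labels, cap=512))
        history.val_acc.append(_accuracy(encoder, val_images, val_labels))
        if history.val_acc[-1] > history.best_val_acc:
            history.best_val_acc = history.val_acc[-1]
            history.best_epoch = epoch
            best_state = encoder.state_dict()
    encoder.load_state_dict(best_state)
    return history
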