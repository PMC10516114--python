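"""Multimodal fusion model: image embedding z1 and mechanical embedding z2
are concatenated (z1 first, then z2) and classified by a fully connected
head: Linear -> BatchNorm -> ReLU (to h2), Linear -> BatchNorm -> ReLU
(to h3), Linear -> Softmax (to n_classes).

The image branch is the residual encoder with its classification layer
replaced by the identity; the mechanical branch is a small feed-forward
network (d -> 32 -> 16 by default) whose 16-wide activation is z2.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import nn
from .encoder import Encoder, EncoderConfig, LeakageError, TrainHistory, check_disjoint_cells

__all__ = [
    "Example",
    "ExampleSet",
    "FusionConfig",
    "MIMLModel",
    "build_fusion",
    "train_miml",
    "extract_latent",
    "fine_tune",
    "save_checkpoint",
    "load_checkpoint",
]

FREEZE_POLICIES = ("none", "encoder", "all-but-head")


@dataclass(frozen=True)
class Example:
    """One training unit: an image, the cell's mechanical vector, a label."""

    image: np.ndarray  # (C, H, W) in [0, 1]
    mech: np.ndarray  # (d,) normalized
    cell_id: str
    label: int | None = None


@dataclass
class ExampleSet:
    """Column-oriented batch of examples."""

    images: np.ndarray  # (N, C, H, W)
    mech: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,)
    cell_ids: list[str]

    def __len__(self) -> int:
        return len(self.cell_ids)

    @classmethod
    def from_examples(cls, examples: list[Example]) -> "ExampleSet":
        missing = [e.cell_id for e in examples if e.mech is None or np.any(~np.isfinite(e.mech))]
        if missing:
            raise ValueError(f"missing/invalid mechanical vector for cells: {missing[:5]}")
        return cls(
            images=np.stack([e.image for e in examples]),
            mech=np.stack([e.mech for e in examples]),
            labels=np.asarray([-1 if e.label is None else e.label for e in examples]),
            cell_ids=[e.cell_id for e in examples],
        )

    def subset(self, idx: np.ndarray) -> "ExampleSet":
        return ExampleSet(
            images=self.images[idx],
            mech=self.mech[idx],
            labels=self.labels[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
        )


@dataclass(frozen=True)
class FusionConfig:
    n_cnn: int = 512  # width of z1 (encoder embedding)
    n_mlp: int = 16  # width of z2
    h2_dim: int = 64
    h3_dim: int = 16
    n_classes: int = 2
    d: int = 3  # mechanical input width
    mech_hidden: tuple[int, ...] = (32, 16)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.d < 1:
            raise ValueError("mechanical input width d must be >= 1")
        if self.mech_hidden[-1] != self.n_mlp:
            raise ValueError(
                f"last mechanical hidden width {self.mech_hidden[-1]} must equal n_mlp={self.n_mlp}"
            )

    @property
    def fused_width(self) -> int:
        return self.n_cnn + self.n_mlp


class MIMLModel:
    """Joint image + mechanics classifier with manual backprop."""

    def __init__(self, encoder_cfg: EncoderConfig, fusion_cfg: FusionConfig, seed: int = 0):
        if encoder_cfg.head != "identity":
            encoder_cfg = replace(encoder_cfg, head="identity")
        if fusion_cfg.n_cnn != encoder_cfg.embedding_width:
            raise ValueError(
                f"n_cnn={fusion_cfg.n_cnn} does not match encoder embedding width "
                f"{encoder_cfg.embedding_width}"
            )
        self.encoder_cfg = encoder_cfg
        self.fusion_cfg = fusion_cfg
        self.encoder = Encoder(encoder_cfg, seed=seed)
        rng = np.random.default_rng([seed, 1])
        mech_layers: list[tuple[str, nn.Layer]] = []
        d_prev = fusion_cfg.d
        for i, width in enumerate(fusion_cfg.mech_hidden, start=1):
            mech_layers.append((f"fc{i}", nn.Linear(d_prev, width, rng)))
            mech_layers.append((f"relu{i}", nn.ReLU()))
            d_prev = width
        self.mech_branch = nn.Sequential(mech_layers)
        rng2 = np.random.default_rng([seed, 2])
        self.head = nn.Sequential(
            [
                ("fc1", nn.Linear(fusion_cfg.fused_width, fusion_cfg.h2_dim, rng2)),
                ("bn1", nn.BatchNorm1d(fusion_cfg.h2_dim)),
                ("relu1", nn.ReLU()),
                ("fc2", nn.Linear(fusion_cfg.h2_dim, fusion_cfg.h3_dim, rng2)),
                ("bn2", nn.BatchNorm1d(fusion_cfg.h3_dim)),
                ("relu2", nn.ReLU()),
                ("fc3", nn.Linear(fusion_cfg.h3_dim, fusion_cfg.n_classes, rng2)),
            ]
        )
        self.freeze_policy = "none"
        self.class_map: dict[int, str] = {}
        self.norm_bounds: dict[str, tuple[float, float]] = {}

    # -- forward / backward ----------------------------------------------
    def forward(self, images: np.ndarray, mech: np.ndarray, train: bool = False,
                return_latent: bool = False):
        """Logits per example; optionally also the fused latent u = [z1; z2]."""
        if mech.shape[1] != self.fusion_cfg.d:
            raise ValueError(f"mechanical vector width {mech.shape[1]} != d={self.fusion_cfg.d}")
        enc_train = train and self.freeze_policy not in ("encoder", "all-but-head")
        mech_train = train and self.freeze_policy != "all-but-head"
        z1 = self.encoder.forward(images, train=enc_train)
        z2 = self.mech_branch.forward(mech, train=mech_train)
        u = np.concatenate([z1, z2], axis=1)
        logits = self.head.forward(u, train=train)
        if return_latent:
            return logits, u
        return logits

    def predict_proba(self, images: np.ndarray, mech: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(images, mech, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        du = self.head.backward(dlogits)
        n_cnn = self.fusion_cfg.n_cnn
        self.encoder.backward(du[:, :n_cnn])
        self.mech_branch.backward(du[:, n_cnn:])

    # -- parameters -------------------------------------------------------
    def parameters(self) -> dict[str, nn.Param]:
        out = {f"encoder.{k}": p for k, p in self.encoder.parameters().items()}
        out.update({f"mech.{k}": p for k, p in self.mech_branch.parameters().items()})
        out.update({f"head.{k}": p for k, p in self.head.parameters().items()})
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"encoder.{k}": v for k, v in self.encoder.state_dict().items()}
        out.update({f"mech.{k}": p.value.copy() for k, p in self.mech_branch.parameters().items()})
        out.update({f"head.{k}": p.value.copy() for k, p in self.head.parameters().items()})
        out.update({f"buf.head.{k}": v.copy() for k, v in self.head.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        enc = {k[8:]: v for k, v in state.items() if k.startswith("encoder.")}
        self.encoder.load_state_dict(enc)
        mismatches = []
        for prefix, module in (("mech.", self.mech_branch), ("head.", self.head)):
            for k, p in module.parameters().items():
                key = prefix + k
                if key not in state:
                    raise KeyError(f"missing parameter {key}")
                if state[key].shape != p.value.shape:
                    mismatches.append((key, state[key].shape, p.value.shape))
                else:
                    p.value[...] = state[key]
        if mismatches:
            raise ValueError(f"architecture mismatch with checkpoint: {mismatches}")
        self.head.load_buffers({k[9:]: v for k, v in state.items() if k.startswith("buf.head.")})

    def apply_freeze(self, policy: str) -> None:
        if policy not in FREEZE_POLICIES:
            raise ValueError(f"freeze policy must be one of {FREEZE_POLICIES}, got {policy!r}")
        self.freeze_policy = policy
        for k, p in self.parameters().items():
            if policy == "none":
                p.frozen = False
            elif policy == "encoder":
                p.frozen = k.startswith("encoder.")
            else:  # all-but-head
                p.frozen = not k.startswith("head.")


def build_fusion(
    encoder_cfg: EncoderConfig, fusion_cfg: FusionConfig | None = None, seed: int = 0
) -> MIMLModel:
    if fusion_cfg is None:
        fusion_cfg = FusionConfig(n_cnn=encoder_cfg.embedding_width)
    return MIMLModel(encoder_cfg, fusion_cfg, seed=seed)


def _miml_accuracy(model: MIMLModel, data: ExampleSet, batch_size: int = 128, cap: int | None = None) -> float:
    if cap is not None and len(data) > cap:
        data = data.subset(np.arange(cap))
    correct = 0
    for lo in range(0, len(data), batch_size):
        logits = model.forward(
            data.images[lo : lo + batch_size], data.mech[lo : lo + batch_size], train=False
        )
        correct += int((logits.argmax(axis=1) == data.labels[lo : lo + batch_size]).sum())
    return correct / len(data)


def train_miml(
    model: MIMLModel,
    train_data: ExampleSet,
    val_data: ExampleSet,
    epochs: int = 40,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> TrainHistory:
    """Joint end-to-end training of both branches and the fusion head.

    Splits must be disjoint by cell id (raises :class:`LeakageError`
    otherwise); the best-validation-epoch weights are restored at the end.
    """
    check_disjoint_cells(train_data.cell_ids, val_data.cell_ids)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    history = TrainHistory()
    best_state = model.state_dict()
    history.best_val_acc = -1.0
    n = len(train_data)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            if len(idx) < 2:
                continue
            logits = model.forward(train_data.images[idx], train_data.mech[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, train_data.labels[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        history.train_acc.append(_miml_accuracy(model, train_data, cap=512))
        history.val_acc.append(_miml_accuracy(model, val_data))
        if history.val_acc[-1] > history.best_val_acc:
            history.best_val_acc = history.val_acc[-1]
            history.best_epoch = epoch
            best_state = model.state_dict()
    if epochs > 0:
        model.load_state_dict(best_state)
    return history


def extract_latent(model: MIMLModel, data: ExampleSet, batch_size: int = 128) -> np.ndarray:
    """Fused latents u = [z1; z2], one row per example, in example order."""
    chunks = []
    for lo in range(0, len(data), batch_size):
        _, u = model.forward(
            data.images[lo : lo + batch_size],
            data.mech[lo : lo + batch_size],
            train=False,
            return_latent=True,
        )
        chunks.append(u)
    return np.concatenate(chunks, axis=0)


def fine_tune(
    model: MIMLModel,
    train_data: ExampleSet,
    val_data: ExampleSet,
    epochs: int = 30,
    freeze: str = "none",
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> TrainHistory:
    """Transfer to a new task: re-initialize the final classification layer,
    apply the freeze policy, and train for a short schedule (default 30
    epochs)."""
    rng = np.random.default_rng([seed, 99])
    fc3_old = model.head["fc3"]
    new_fc3 = nn.Linear(fc3_old.W.value.shape[0], fc3_old.W.value.shape[1], rng)
    model.head.layers = [
        (name, new_fc3 if name == "fc3" else layer) for name, layer in model.head.layers
    ]
    model.apply_freeze(freeze)
    return train_miml(model, train_data, val_data, epochs=epochs,
                      batch_size=batch_size, lr=lr, seed=seed)


CHECKPOINT_VERSION = 1


def save_checkpoint(model: MIMLModel, path: str | Path) -> None:
    """Single-file archive: weights + configs + normalization bounds + class map."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "encoder_cfg": asdict(model.encoder_cfg),
        "fusion_cfg": asdict(model.fusion_cfg),
        "class_map": model.class_map,
        "norm_bounds": model.norm_bounds,
        "concat_order": ["z1", "z2"],
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> MIMLModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    enc_cfg = meta["encoder_cfg"]
    enc_cfg["image_size"] = tuple(enc_cfg["image_size"])
    fus_cfg = meta["fusion_cfg"]
    fus_cfg["mech_hidden"] = tuple(fus_cfg["mech_hidden"])
    model = MIMLModel(EncoderConfig(**enc_cfg), FusionConfig(**fus_cfg))
    model.load_state_dict(state)
    model.class_map = {int(k): v for k, v in meta["class_map"].items()}
    model.norm_bounds = {k: tuple(v) for k, v in meta["norm_bounds"].items()}
    return model
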