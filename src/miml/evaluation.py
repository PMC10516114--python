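"""Evaluation toolkit: confusion counts, accuracy/precision/recall/F1,
ROC/AUC, grouped stratified k-fold plans, Grad-CAM heatmaps, and 2-D latent
embeddings.

Metric definitions on the confusion counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)  (= 2PR / (P + R))

Zero-denominator ratios are reported as 0 with a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .encoder import Encoder

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldPlan",
    "confusion",
    "metrics",
    "roc_auc",
    "make_folds",
    "grad_cam",
    "embed_2d",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    counts: ConfusionCounts | None = None
    warnings: list[str] = field(default_factory=list)


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Confusion counts with an explicit positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero counts")
    warns: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            warns.append(f"{name} undefined (zero denominator); reported as 0")
            return 0.0
        return num / den

    return MetricsReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=ratio(counts.tp, counts.tp + counts.fp, "precision"),
        recall=ratio(counts.tp, counts.tp + counts.fn, "recall"),
        f1=ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1"),
        counts=counts,
        warnings=warns,
    )


def roc_auc(y_true, scores, positive=1) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR arrays) and trapezoid AUC.

    Thresholds sweep the unique scores (ties grouped); the curve includes the
    (0,0) and (1,1) endpoints.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    pos = y_true == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep the last index of each tied-score group
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class FoldPlan:
    """k disjoint cell-id folds, stratified by class."""

    folds: list[list[str]]

    @property
    def k(self) -> int:
        return len(self.folds)

    def all_ids(self) -> set[str]:
        return set().union(*map(set, self.folds))

    def validate_partition(self, cell_ids) -> None:
        ids = list(cell_ids)
        union = self.all_ids()
        if union != set(ids):
            raise ValueError("fold plan does not cover exactly the given cell ids")
        if sum(len(f) for f in self.folds) != len(set(ids)):
            raise ValueError("folds overlap")


def make_folds(cell_ids, labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Grouped stratified folds: each cell id lands in exactly one fold and
    per-fold class counts deviate from the global ratio by at most one cell.
    """
    cell_ids = list(cell_ids)
    labels = np.asarray(labels)
    if len(cell_ids) != len(labels):
        raise ValueError("cell_ids and labels length mismatch")
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("cell_ids must be unique (one row per cell)")
    if k > len(cell_ids):
        raise ValueError(f"k={k} exceeds number of cells {len(cell_ids)}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(labels):
        members = [cid for cid, y in zip(cell_ids, labels) if y == cls]
        if k > len(members):
            raise ValueError(f"k={k} exceeds count of class {cls!r} ({len(members)})")
        members = [members[i] for i in rng.permutation(len(members))]
        for i, cid in enumerate(members):
            folds[(i + offset) % k].append(cid)
        offset += len(members) % k  # rotate so remainders spread across folds
    return FoldPlan(folds=folds)


def grad_cam(
    model: Encoder,
    image: np.ndarray,
    layer: str = "last",
    target_class: int | None = None,
) -> np.ndarray:
    """Gradient-weighted class-activation heatmap, aligned to the image.

    ``layer`` is 'last' or 'penultimate' (the final convolutional output of
    the last / next-to-last encoder stage) or an explicit layer name. The map
    is channel-weighted by the spatially averaged gradient of the target
    class logit, rectified, upsampled to the image size and min-max scaled
    to [0, 1].
    """
    if image.ndim == 2:
        image = image[None, :, :]
    batch = image[None, ...].astype(float)
    target_name = model.stage_output_layer(layer)
    x = batch
    activations = None
    after: list = []
    for name, lyr in model.net.layers:
        x = lyr.forward(x, train=False)
        if name == target_name:
            activations = x
            after = []
        else:
            after.append(lyr)
    if activations is None:
        raise KeyError(f"layer {target_name!r} not found in encoder")
    logits = model.fc.forward(x, train=False)
    if target_class is None:
        target_class = int(np.argmax(logits[0]))
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dy = model.fc.backward(dlogits)
    for lyr in reversed(after):
        dy = lyr.backward(dy)
    grads = dy  # gradient w.r.t. the target activations, (1, C, h, w)
    weights = grads.mean(axis=(2, 3))[0]  # (C,)
    cam = np.maximum((weights[:, None, None] * activations[0]).sum(axis=0), 0.0)
    cam = resize(cam, image.shape[1:], order=1, mode="edge", anti_aliasing=False)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return cam


def embed_2d(latents: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE projection of latent vectors to 2-D; deterministic given seed."""
    from sklearn.manifold import TSNE

    latents = np.asarray(latents, dtype=float)
    n = latents.shape[0]
    if n < 5:
        raise ValueError(
            f"need at least 5 rows for a 2-D embedding, got {n}; "
            "collect more examples or plot the raw features instead"
        )
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(latents)


def plot_embedding(coords, labels, path, highlight=None):  # pragma: no cover - I/O helper
    """Scatter plot of a 2-D embedding, optionally marking selected points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(labels):
        sel = labels == cls
        ax.scatter(coords[sel, 0], coords[sel, 1], s=8, alpha=0.7, label=str(cls))
    if highlight is not None:
        ax.scatter(coords[highlight, 0], coords[highlight, 1], s=60, facecolors="none",
                   edgecolors="k", label="selected")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
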