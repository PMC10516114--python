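"""Classifiers over the mechanical feature vector.

Six model kinds: logistic regression, RBF support-vector machine, decision
tree, random forest, k-nearest neighbours (scikit-learn), and a small
feed-forward network (d -> 32 -> 16 -> 2; 706 trainable parameters for
d = 3) implemented on the in-package NumPy layers so it shares code with the
fusion model's mechanical branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import nn

__all__ = [
    "MODEL_KINDS",
    "FeatureMatrix",
    "TabularModelSpec",
    "FeatureMLP",
    "fit_classifier",
    "fit_feature_mlp",
    "compare_models",
]

MODEL_KINDS = ("lr", "svm", "dt", "rf", "knn", "mlp")


@dataclass
class FeatureMatrix:
    """Rows = cells, columns = normalized mechanical features, binary labels."""

    X: np.ndarray  # (n, d), entries in [0, 1]
    y: np.ndarray  # (n,), labels in {0, 1}
    cell_ids: list[str]
    feature_names: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError(f"shape mismatch: X {self.X.shape}, y {self.y.shape}")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.X.size and (self.X.min() < -1e-9 or self.X.max() > 1 + 1e-9):
            raise ValueError("features must be normalized to [0, 1]")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match number of columns")

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.X[:, idx], self.y, self.cell_ids, list(names))


@dataclass(frozen=True)
class TabularModelSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


class FeatureMLP:
    """Feed-forward net d -> 32 -> 16 -> n_classes with ReLU hidden layers."""

    def __init__(self, d: int, hidden: tuple[int, int] = (32, 16), n_classes: int = 2, seed: int = 0):
        if d < 1:
            raise ValueError("input width d must be >= 1")
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            [
                ("fc1", nn.Linear(d, hidden[0], rng)),
                ("relu1", nn.ReLU()),
                ("fc2", nn.Linear(hidden[0], hidden[1], rng)),
                ("relu2", nn.ReLU()),
                ("fc3", nn.Linear(hidden[1], n_classes, rng)),
            ]
        )
        self.d = d

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.net.parameters().values())

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 200,
        lr: float = 1e-3,
        batch_size: int = 32,
        val_fraction: float = 0.2,
        patience: int = 20,
        seed: int = 0,
    ) -> "FeatureMLP":
        """Cross-entropy training with early stop on a validation plateau."""
        rng = np.random.default_rng(seed)
        n = len(y)
        order = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n > 5 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        opt = nn.Adam(self.net.parameters(), lr=lr)
        best_loss, best_state, waited = np.inf, None, 0
        for _ in range(epochs):
            perm = rng.permutation(len(tr_idx))
            for lo in range(0, len(tr_idx), batch_size):
                idx = tr_idx[perm[lo : lo + batch_size]]
                if idx.size == 0:
                    continue
                logits = self.net.forward(X[idx], train=True)
                _, dlogits = nn.cross_entropy(logits, y[idx])
                opt.zero_grad()
                self.net.backward(dlogits)
                opt.step()
            if n_val:
                val_loss, _ = nn.cross_entropy(self.net.forward(X[val_idx]), y[val_idx])
                if val_loss < best_loss - 1e-5:
                    best_loss, waited = val_loss, 0
                    best_state = {k: p.value.copy() for k, p in self.net.parameters().items()}
                else:
                    waited += 1
                    if waited >= patience:
                        break
        if best_state is not None:
            for k, p in self.net.parameters().items():
                p.value[...] = best_state[k]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.net.forward(np.asarray(X, dtype=float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def _sklearn_model(spec: TabularModelSpec):
    hp = dict(spec.hyperparams)
    if spec.kind == "lr":
        # default penalty is already L2
        return LogisticRegression(C=hp.pop("C", 1.0), max_iter=1000, **hp)
    if spec.kind == "svm":
        return SVC(C=hp.pop("C", 1.0), kernel=hp.pop("kernel", "rbf"), gamma=hp.pop("gamma", "scale"),
                   probability=True, random_state=spec.seed, **hp)
    if spec.kind == "dt":
        return DecisionTreeClassifier(criterion=hp.pop("criterion", "gini"),
                                      random_state=spec.seed, **hp)
    if spec.kind == "rf":
        return RandomForestClassifier(n_estimators=hp.pop("n_estimators", 100),
                                      random_state=spec.seed, **hp)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), metric=hp.pop("metric", "minkowski"), **hp)
    raise AssertionError(spec.kind)


def fit_classifier(spec: TabularModelSpec, fm: FeatureMatrix):
    """Fit one model kind; returns a handle with predict / predict_proba."""
    if len(np.unique(fm.y)) < 2:
        raise ValueError("single-class input: need at least 2 rows per class")
    counts = np.bincount(fm.y, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"need >= 2 rows per class, got counts {counts.tolist()}")
    if spec.kind == "mlp":
        mlp = FeatureMLP(fm.X.shape[1], seed=spec.seed)
        mlp.fit(fm.X, fm.y, seed=spec.seed, **spec.hyperparams)
        return mlp
    model = _sklearn_model(spec)
    model.fit(fm.X, fm.y)
    return model


def fit_feature_mlp(fm: FeatureMatrix, seed: int = 0, **fit_kwargs) -> FeatureMLP:
    """The d -> 32 -> 16 -> 2 network on mechanical features."""
    mlp = FeatureMLP(fm.X.shape[1], seed=seed)
    mlp.fit(fm.X, fm.y, seed=seed, **fit_kwargs)
    return mlp


def compare_models(
    fm: FeatureMatrix,
    fold_plan,
    kinds: tuple[str, ...] = MODEL_KINDS,
    feature_sets: list[list[str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated accuracy per model kind and feature subset.

    Every model sees the same fold plan (grouped by cell id); the result has
    one row per (model, feature set) with mean and sd accuracy over folds.
    """
    from .evaluation import FoldPlan  # local import to avoid a cycle

    if feature_sets is None:
        feature_sets = [fm.feature_names]
    id_to_row = {cid: i for i, cid in enumerate(fm.cell_ids)}
    records = []
    for names in feature_sets:
        sub = fm.select(names)
        for kind in kinds:
            fold_accs = []
            for fold_idx, test_ids in enumerate(fold_plan.folds):
                test_rows = np.asarray(sorted(id_to_row[c] for c in test_ids))
                train_rows = np.asarray(sorted(set(range(len(fm.y))) - set(test_rows)))
                spec = TabularModelSpec(kind=kind, seed=seed)
                model = fit_classifier(
                    spec,
                    FeatureMatrix(sub.X[train_rows], sub.y[train_rows],
                                  [sub.cell_ids[i] for i in train_rows], sub.feature_names),
                )
                acc = float((model.predict(sub.X[test_rows]) == sub.y[test_rows]).mean())
                fold_accs.append(acc)
                records.append(
                    {"model": kind, "features": "+".join(names), "fold": fold_idx, "accuracy": acc}
                )
    df = pd.DataFrame.from_records(records)
    summary = (
        df.groupby(["model", "features"])["accuracy"].agg(["mean", "std"]).reset_index()
    )
    summary.attrs["per_fold"] = df
    return summary
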