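"""Experiment orchestration: manifest I/O, leakage-safe splits, dataset
assembly, and the end-to-end recipes (tabular / cnn / miml / miml+dir /
transfer).

Splitting protocol: cells are first partitioned train+val : test = 4 : 1,
stratified by class and grouped by cell id; k-fold cross-validation runs
inside the 80 % portion. Every random operation draws from a named
substream of the single run seed so stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .encoder import Encoder, EncoderConfig, train_image_classifier
from .evaluation import FoldPlan, confusion, make_folds, metrics, roc_auc
from .features import MinMaxNormalizer
from .fusion import (
    ExampleSet,
    FusionConfig,
    MIMLModel,
    build_fusion,
    fine_tune,
    load_checkpoint,
    save_checkpoint,
    train_miml,
)
from .synthetic import MANIFEST_COLUMNS
from .tabular import FeatureMatrix, compare_models

__all__ = [
    "RunConfig",
    "ExperimentReport",
    "substream",
    "read_manifest",
    "write_manifest",
    "split_dataset",
    "load_example_sets",
    "feature_matrix_from_manifest",
    "run_experiment",
    "evaluate_model",
]

FEATURE_COLUMNS = {"di": "di", "tt": "tt_ms", "vmax": "vmax_norm", "dir": "dir_per_ms"}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the run seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class RunConfig:
    seed: int = 0
    test_fraction: float = 0.2
    k_folds: int = 5
    features: tuple[str, ...] = ("di", "tt", "vmax")
    epochs: int = 15
    batch_size: int = 32
    lr: float = 1e-3
    base_filters: int = 8
    stages: int = 3
    blocks_per_stage: int = 1
    image_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        unknown = set(self.features) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}; choose from {sorted(FEATURE_COLUMNS)}")

    def encoder_config(self, head: str = "classifier") -> EncoderConfig:
        return EncoderConfig(
            base_filters=self.base_filters,
            stages=self.stages,
            blocks_per_stage=self.blocks_per_stage,
            image_size=self.image_size,
            head=head,
        )


@dataclass
class ExperimentReport:
    recipe: str
    config: dict
    per_fold: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    environment: dict = field(default_factory=lambda: {
        "python": platform.python_version(),
        "numpy": np.__version__,
    })

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


# ---------------------------------------------------------------------------
# manifest I/O


def read_manifest(path: str | Path, check_images: bool = False) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "class": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required column(s): {missing}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id in manifest: {dup}")
    if check_images:
        root = path.parent
        for _, row in df.iterrows():
            for col in ("img_entry", "img_squeezed"):
                if not (root / row[col]).exists():
                    raise FileNotFoundError(
                        f"cell {row['cell_id']}: image file not found: {root / row[col]}"
                    )
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write manifest, missing column(s): {missing}")
    ordered = MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]
    df[ordered].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splits


def split_dataset(
    manifest: pd.DataFrame, config: RunConfig
) -> tuple[list[str], list[str]]:
    """Stratified cell-level split into (train+val ids, test ids)."""
    rng = substream(config.seed, "splits")
    trainval: list[str] = []
    test: list[str] = []
    for cls, group in manifest.groupby("class"):
        ids = group["cell_id"].tolist()
        n_test = int(round(config.test_fraction * len(ids)))
        if len(ids) - n_test < config.k_folds:
            raise ValueError(
                f"class {cls!r} has too few cells ({len(ids)}) for "
                f"{config.k_folds}-fold CV after the test split"
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        test.extend(ids[:n_test])
        trainval.extend(ids[n_test:])
    return sorted(trainval), sorted(test)


# ---------------------------------------------------------------------------
# dataset assembly


def _load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return arr[None, :, :]  # (1, H, W)


def _class_map(manifest: pd.DataFrame) -> dict[str, int]:
    classes = sorted(manifest["class"].unique())
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, found {classes}")
    return {c: i for i, c in enumerate(classes)}


def load_example_sets(
    manifest: pd.DataFrame,
    root: str | Path,
    splits: dict[str, list[str]],
    features: tuple[str, ...] = ("di", "tt", "vmax"),
    train_key: str = "train",
    frames: tuple[str, ...] = ("entry", "squeezed"),
) -> tuple[dict[str, ExampleSet], dict[str, tuple[float, float]], dict[str, int]]:
    """Build per-split ExampleSets (one example per cell per frame in
    ``frames``; the default uses both the entry and squeezed frames).

    Mechanical features are min-max normalized with bounds fitted on the
    ``train_key`` split only; DI uses the fixed (0, 1) bounds. Returns the
    example sets, the normalization bounds, and the class map.
    """
    frame_cols = {"entry": "img_entry", "squeezed": "img_squeezed"}
    bad = set(frames) - set(frame_cols)
    if bad:
        raise ValueError(f"unknown frames {sorted(bad)}; choose from {sorted(frame_cols)}")
    root = Path(root)
    cmap = _class_map(manifest)
    df = manifest.set_index("cell_id", drop=False)
    train_ids = splits[train_key]
    bounds: dict[str, tuple[float, float]] = {}
    normalizers: dict[str, MinMaxNormalizer] = {}
    for feat in features:
        col = FEATURE_COLUMNS[feat]
        if feat == "di":
            norm = MinMaxNormalizer(bounds=(0.0, 1.0))
        else:
            norm = MinMaxNormalizer().fit(df.loc[train_ids, col].to_numpy())
        normalizers[feat] = norm
        bounds[feat] = (norm.lo, norm.hi)
    sets: dict[str, ExampleSet] = {}
    for split_name, ids in splits.items():
        images, mech, labels, cell_ids = [], [], [], []
        for cid in ids:
            row = df.loc[cid]
            vec = np.array(
                [normalizers[f].transform(np.array([row[FEATURE_COLUMNS[f]]]))[0] for f in features]
            )
            for frame in frames:
                images.append(_load_image(root / row[frame_cols[frame]]))
                mech.append(vec)
                labels.append(cmap[row["class"]])
                cell_ids.append(cid)
        sets[split_name] = ExampleSet(
            images=np.stack(images) if images else np.empty((0, 1, 1, 1)),
            mech=np.stack(mech) if mech else np.empty((0, len(features))),
            labels=np.asarray(labels),
            cell_ids=cell_ids,
        )
    return sets, bounds, cmap


def feature_matrix_from_manifest(
    manifest: pd.DataFrame,
    features: tuple[str, ...] = ("di", "tt", "vmax"),
    train_ids: list[str] | None = None,
) -> FeatureMatrix:
    """One row per cell, min-max normalized (bounds from train_ids if given)."""
    cmap = _class_map(manifest)
    fit_df = manifest if train_ids is None else manifest[manifest["cell_id"].isin(train_ids)]
    cols = []
    for feat in features:
        col = FEATURE_COLUMNS[feat]
        norm = (
            MinMaxNormalizer(bounds=(0.0, 1.0))
            if feat == "di"
            else MinMaxNormalizer().fit(fit_df[col].to_numpy())
        )
        cols.append(norm.transform(manifest[col].to_numpy()))
    return FeatureMatrix(
        X=np.column_stack(cols),
        y=manifest["class"].map(cmap).to_numpy(),
        cell_ids=manifest["cell_id"].tolist(),
        feature_names=list(features),
    )


# ---------------------------------------------------------------------------
# evaluation helpers


def _per_cell_predictions(probs: np.ndarray, cell_ids: list[str], labels: np.ndarray):
    """Average per-image probabilities per cell."""
    order: dict[str, int] = {}
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    truth: dict[str, int] = {}
    for p, cid, y in zip(probs, cell_ids, labels):
        if cid not in order:
            order[cid] = len(order)
            sums[cid] = np.zeros_like(p)
            counts[cid] = 0
            truth[cid] = int(y)
        sums[cid] += p
        counts[cid] += 1
    ids = sorted(order, key=order.get)
    avg = np.stack([sums[c] / counts[c] for c in ids])
    y_true = np.asarray([truth[c] for c in ids])
    return ids, avg, y_true


def evaluate_model(probs: np.ndarray, cell_ids: list[str], labels: np.ndarray) -> dict:
    """Per-image and per-cell metric reports from predicted probabilities."""
    out: dict = {}
    y_pred = probs.argmax(axis=1)
    rep = metrics(confusion(labels, y_pred))
    _, _, auc = roc_auc(labels, probs[:, 1])
    out["per_image"] = {
        "accuracy": rep.accuracy, "precision": rep.precision,
        "recall": rep.recall, "f1": rep.f1, "auc": auc,
    }
    _, avg, y_true = _per_cell_predictions(probs, cell_ids, labels)
    rep_c = metrics(confusion(y_true, avg.argmax(axis=1)))
    _, _, auc_c = roc_auc(y_true, avg[:, 1])
    out["per_cell"] = {
        "accuracy": rep_c.accuracy, "precision": rep_c.precision,
        "recall": rep_c.recall, "f1": rep_c.f1, "auc": auc_c,
    }
    return out


# ---------------------------------------------------------------------------
# recipes


def _train_eval_cnn(sets, config: RunConfig, seed: int) -> tuple[Encoder, dict]:
    enc = Encoder(config.encoder_config("classifier"), seed=seed)
    train, val = sets["train"], sets["val"]
    train_image_classifier(
        enc, train.images, train.labels, val.images, val.labels,
        train_cell_ids=train.cell_ids, val_cell_ids=val.cell_ids,
        epochs=config.epochs, batch_size=config.batch_size, lr=config.lr, seed=seed,
    )
    from .nn import softmax

    report = {}
    for name in ("val", "test"):
        if name in sets and len(sets[name]):
            probs = softmax(enc.forward(sets[name].images, train=False))
            report[name] = evaluate_model(probs, sets[name].cell_ids, sets[name].labels)
    return enc, report


def _train_eval_miml(sets, config: RunConfig, seed: int, d: int) -> tuple[MIMLModel, dict]:
    enc_cfg = config.encoder_config("identity")
    fus_cfg = FusionConfig(n_cnn=enc_cfg.embedding_width, d=d)
    model = build_fusion(enc_cfg, fus_cfg, seed=seed)
    train_miml(model, sets["train"], sets["val"], epochs=config.epochs,
               batch_size=config.batch_size, lr=config.lr, seed=seed)
    report = {}
    for name in ("val", "test"):
        if name in sets and len(sets[name]):
            probs = model.predict_proba(sets[name].images, sets[name].mech)
            report[name] = evaluate_model(probs, sets[name].cell_ids, sets[name].labels)
    return model, report


def run_experiment(
    recipe: str,
    manifest_path: str | Path,
    config: RunConfig,
    checkpoint_out: str | Path | None = None,
    pretrained: str | Path | None = None,
) -> ExperimentReport:
    """Execute one end-to-end recipe on a dataset manifest.

    Recipes: 'tabular' (six-model comparison), 'cnn' (image-only), 'miml'
    (fusion, d=3), 'miml+dir' (fusion, d=4), 'transfer' (fine-tune a
    pretrained checkpoint). Cross-validation folds are shared across models.
    """
    recipes = ("tabular", "cnn", "miml", "miml+dir", "transfer")
    if recipe not in recipes:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {recipes}")
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    features = config.features + (("dir",) if recipe == "miml+dir" and "dir" not in config.features else ())
    report = ExperimentReport(recipe=recipe, config={**asdict(config), "features": list(features)})
    trainval_ids, test_ids = split_dataset(manifest, config)
    tv_labels = manifest.set_index("cell_id").loc[trainval_ids, "class"].to_numpy()
    plan = make_folds(trainval_ids, tv_labels, k=config.k_folds,
                      seed=int(substream(config.seed, "folds").integers(2**31)))

    if recipe == "tabular":
        fm = feature_matrix_from_manifest(manifest[manifest["cell_id"].isin(trainval_ids)],
                                          features=features)
        summary = compare_models(fm, plan, seed=config.seed)
        report.per_fold = summary.attrs["per_fold"].to_dict("records")
        report.summary = summary.to_dict("records")
        return report

    d = len(features)
    accs: dict[str, list[float]] = {"train": [], "val": [], "test": []}
    best_model = None
    best_val = -1.0
    for fold_idx, val_ids in enumerate(plan.folds):
        train_ids = sorted(set(trainval_ids) - set(val_ids))
        sets, bounds, cmap = load_example_sets(
            manifest, root,
            {"train": train_ids, "val": sorted(val_ids), "test": test_ids},
            features=features,
        )
        seed_fold = int(substream(config.seed, f"fold{fold_idx}").integers(2**31))
        if recipe == "cnn":
            model, fold_report = _train_eval_cnn(sets, config, seed_fold)
        elif recipe in ("miml", "miml+dir"):
            model, fold_report = _train_eval_miml(sets, config, seed_fold, d=d)
        else:  # transfer
            if pretrained is None:
                raise ValueError("recipe 'transfer' requires a pretrained checkpoint")
            model = load_checkpoint(pretrained)
            fine_tune(model, sets["train"], sets["val"], epochs=config.epochs,
                      freeze="none", batch_size=config.batch_size, lr=config.lr, seed=seed_fold)
            fold_report = {}
            for name in ("val", "test"):
                probs = model.predict_proba(sets[name].images, sets[name].mech)
                fold_report[name] = evaluate_model(probs, sets[name].cell_ids, sets[name].labels)
        entry = {"fold": fold_idx, **{k: v for k, v in fold_report.items()}}
        report.per_fold.append(entry)
        for split in ("val", "test"):
            if split in fold_report:
                accs[split].append(fold_report[split]["per_cell"]["accuracy"])
        if fold_report.get("val", {}).get("per_cell", {}).get("accuracy", -1) > best_val:
            best_val = fold_report["val"]["per_cell"]["accuracy"]
            best_model = model
            if isinstance(model, MIMLModel):
                model.class_map = {v: k for k, v in cmap.items()}
                model.norm_bounds = bounds
    report.summary = {
        f"{split}_{stat}": float(fn(vals))
        for split, vals in accs.items() if vals
        for stat, fn in (("mean", np.mean), ("sd", np.std))
    }
    if checkpoint_out is not None and isinstance(best_model, MIMLModel):
        save_checkpoint(best_model, checkpoint_out)
    return report
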