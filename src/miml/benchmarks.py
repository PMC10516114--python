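"""Canonical benchmark regimes for the fusion model.

Three constructed data regimes, each a :class:`PopulationConfig` factory plus
a runner that generates the dataset, trains the relevant models and returns
held-out accuracies:

* fusion benefit — classes share diameter and appearance (texture overlap 1)
  and differ only in stiffness with a moderate mechanical effect size
  (Cohen's d ≈ 2 per feature). Images are entry frames of undeformed cells,
  so image-only classification sits at chance while the mechanical branch
  carries the class signal.
* no harm — classes share stiffness (mechanics uninformative) and differ in
  texture (overlap 0), so the image branch carries the signal and fusion
  must not degrade it.
* transfer — a strongly separable source task and a stiffness-shifted target
  task used to measure fine-tuning with ~1/30 of the training data.

Entry-frame-only inputs are used throughout so the rendered cell shape does
not leak the deformation index into the image route.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .encoder import Encoder
from .evaluation import make_folds
from .fusion import fine_tune, load_checkpoint, save_checkpoint
from .synthetic import ClassConfig, PopulationConfig, make_dataset
from .tabular import fit_feature_mlp
from .workflow import (
    RunConfig,
    _train_eval_cnn,
    _train_eval_miml,
    feature_matrix_from_manifest,
    load_example_sets,
    read_manifest,
    split_dataset,
    substream,
)

__all__ = [
    "fusion_benefit_population",
    "no_harm_population",
    "transfer_population",
    "prepare_benchmark_sets",
    "run_fusion_benefit",
    "run_no_harm",
    "run_transfer",
    "run_di_roundtrip",
    "run_monotonicity",
    "run_gradcam_localization",
]


def _two_class(
    n: int,
    stiff_soft: tuple[float, float],
    stiff_stiff: tuple[float, float],
    overlap: float,
    seed: int,
    diameter: tuple[float, float] = (14.0, 1.2),
) -> PopulationConfig:
    soft = ClassConfig(
        name="soft", n=n, diameter_mean=diameter[0], diameter_sd=diameter[1],
        stiffness_mean=stiff_soft[0], stiffness_sd=stiff_soft[1],
        texture_sigma=3.0, texture_amp=0.10, brightness=0.80,
    )
    stiff = ClassConfig(
        name="stiff", n=n, diameter_mean=diameter[0], diameter_sd=diameter[1],
        stiffness_mean=stiff_stiff[0], stiffness_sd=stiff_stiff[1],
        texture_sigma=1.0, texture_amp=0.22, brightness=0.62,
    )
    return PopulationConfig(classes=(soft, stiff), texture_overlap=overlap, seed=seed)


def fusion_benefit_population(n_per_class: int = 300, seed: int = 0) -> PopulationConfig:
    """Mechanics-separable (d ~ 2), visually indistinguishable classes."""
    return _two_class(n_per_class, (4.0, 1.1), (6.8, 1.7), overlap=1.0, seed=seed)


def no_harm_population(n_per_class: int = 300, seed: int = 0) -> PopulationConfig:
    """Mechanics-uninformative, visually separable classes."""
    return _two_class(n_per_class, (5.0, 1.2), (5.0, 1.2), overlap=0.0, seed=seed)


def transfer_population(
    n_per_class: int = 300, seed: int = 0, shifted: bool = False
) -> PopulationConfig:
    """Strongly mechanics-separable task; ``shifted=True`` moves both classes
    to a stiffer regime (the transfer target)."""
    if shifted:
        return _two_class(n_per_class, (3.0, 0.6), (12.0, 2.4), overlap=1.0, seed=seed)
    return _two_class(n_per_class, (1.5, 0.3), (7.0, 1.4), overlap=1.0, seed=seed)


def prepare_benchmark_sets(
    pop: PopulationConfig,
    out_dir: str | Path,
    config: RunConfig,
    frames: tuple[str, ...] = ("entry",),
):
    """Generate the dataset, split it, and build a single train/val/test
    ExampleSet triple (first CV fold as validation)."""
    summary = make_dataset(pop, out_dir=out_dir)
    manifest = read_manifest(summary["manifest"])
    trainval, test = split_dataset(manifest, config)
    labels = manifest.set_index("cell_id").loc[trainval, "class"].to_numpy()
    plan = make_folds(trainval, labels, k=config.k_folds,
                      seed=int(substream(config.seed, "folds").integers(2**31)))
    val_ids = sorted(plan.folds[0])
    train_ids = sorted(set(trainval) - set(val_ids))
    sets, bounds, cmap = load_example_sets(
        manifest, Path(out_dir),
        {"train": train_ids, "val": val_ids, "test": test},
        features=config.features, frames=frames,
    )
    return manifest, sets, bounds, cmap


def run_fusion_benefit(out_dir: str | Path, seed: int, n_per_class: int = 300,
                       epochs: int = 5) -> dict:
    """Train MIML, image-only CNN and feature-MLP on the fusion-benefit
    regime; returns held-out (test) per-cell accuracies."""
    config = RunConfig(seed=seed, epochs=epochs, k_folds=4)
    pop = fusion_benefit_population(n_per_class, seed=seed)
    manifest, sets, _, _ = prepare_benchmark_sets(pop, out_dir, config)
    _, cnn_rep = _train_eval_cnn(sets, config, seed=seed)
    _, miml_rep = _train_eval_miml(sets, config, seed=seed, d=len(config.features))
    train_ids = set(sets["train"].cell_ids)
    fm_all = feature_matrix_from_manifest(manifest, features=config.features,
                                          train_ids=sorted(train_ids))
    in_train = np.array([c in train_ids for c in fm_all.cell_ids])
    in_test = np.array([c in set(sets["test"].cell_ids) for c in fm_all.cell_ids])
    mlp = fit_feature_mlp(
        type(fm_all)(fm_all.X[in_train], fm_all.y[in_train],
                     [c for c, m in zip(fm_all.cell_ids, in_train) if m], fm_all.feature_names),
        seed=seed,
    )
    mlp_acc = float((mlp.predict(fm_all.X[in_test]) == fm_all.y[in_test]).mean())
    return {
        "cnn": cnn_rep["test"]["per_cell"]["accuracy"],
        "miml": miml_rep["test"]["per_cell"]["accuracy"],
        "feature_mlp": mlp_acc,
    }


def run_no_harm(out_dir: str | Path, seed: int, n_per_class: int = 300,
                epochs: int = 5) -> dict:
    """CNN vs MIML when mechanics are uninformative and images separable."""
    config = RunConfig(seed=seed, epochs=epochs, k_folds=4)
    pop = no_harm_population(n_per_class, seed=seed)
    _, sets, _, _ = prepare_benchmark_sets(pop, out_dir, config)
    _, cnn_rep = _train_eval_cnn(sets, config, seed=seed)
    _, miml_rep = _train_eval_miml(sets, config, seed=seed, d=len(config.features))
    return {
        "cnn": cnn_rep["test"]["per_cell"]["accuracy"],
        "miml": miml_rep["test"]["per_cell"]["accuracy"],
    }


def run_transfer(out_dir: str | Path, seed: int, n_per_class: int = 300,
                 pretrain_epochs: int = 5, finetune_epochs: int = 30,
                 small_fraction: float = 1 / 30) -> dict:
    """Fine-tune a pretrained fusion model on a stiffness-shifted target with
    ~``small_fraction`` of the training cells vs training from scratch on the
    full-size target set."""
    out_dir = Path(out_dir)
    config = RunConfig(seed=seed, epochs=pretrain_epochs, k_folds=4)
    # source task + pretrained model
    src_pop = transfer_population(n_per_class, seed=seed, shifted=False)
    _, src_sets, _, _ = prepare_benchmark_sets(src_pop, out_dir / "source", config)
    model, _ = _train_eval_miml(src_sets, config, seed=seed, d=len(config.features))
    ckpt = out_dir / "source.npz"
    save_checkpoint(model, ckpt)
    # target task
    tgt_pop = transfer_population(n_per_class, seed=seed + 1, shifted=True)
    _, tgt_sets, _, _ = prepare_benchmark_sets(tgt_pop, out_dir / "target", config)
    full_train = tgt_sets["train"]
    rng = substream(seed, "transfer-subset")
    cells = sorted(set(full_train.cell_ids))
    n_small = max(2, int(round(small_fraction * len(cells))))
    small_cells = set(rng.choice(cells, size=n_small, replace=False))
    small_idx = np.array([i for i, c in enumerate(full_train.cell_ids) if c in small_cells])
    small_train = full_train.subset(small_idx)
    # fine-tune on the small subset; freeze the (uninformative-image) encoder
    # and use small batches so 30 epochs yield enough optimizer steps
    ft_model = load_checkpoint(ckpt)
    fine_tune(ft_model, small_train, tgt_sets["val"], epochs=finetune_epochs,
              freeze="encoder", batch_size=4, lr=5e-3, seed=seed)
    probs = ft_model.predict_proba(tgt_sets["test"].images, tgt_sets["test"].mech)
    from .workflow import evaluate_model

    ft_acc = evaluate_model(probs, tgt_sets["test"].cell_ids, tgt_sets["test"].labels)
    # from scratch on the full-size target training set
    _, scratch_rep = _train_eval_miml(tgt_sets, config, seed=seed, d=len(config.features))
    return {
        "fine_tuned": ft_acc["per_cell"]["accuracy"],
        "from_scratch": scratch_rep["test"]["per_cell"]["accuracy"],
        "n_small_cells": n_small,
        "n_full_cells": len(cells),
    }


def run_di_roundtrip(n: int = 100, seed: int = 0) -> dict:
    """Render ``n`` ellipses with known axes, re-extract DI through the
    segmentation + moment-fit route, and report the error distribution."""
    from . import features as feat
    from .synthetic import CellSpec, ImageSpec, _render_frame

    rng = np.random.default_rng(seed)
    spec = ImageSpec(height=96, width=96, pixel_scale=0.45)
    errors = []
    for i in range(n):
        a = rng.uniform(10.0, 30.0)
        b = rng.uniform(6.0, min(a, 20.0))
        cell = CellSpec(cell_id=f"rt{i}", class_label="x", diameter=10.0,
                        stiffness=1.0, texture_seed=i, texture_amp=0.1)
        img = _render_frame(a, b, cell, spec, np.random.default_rng([seed, i]), "rt")
        fit = feat.fit_ellipse(feat.segment_cell(img), pixel_scale=spec.pixel_scale)
        errors.append(abs(feat.compute_di(fit.a, fit.b) - feat.compute_di(a, b)))
    errors = np.asarray(errors)
    return {"max_error": float(errors.max()), "mean_error": float(errors.mean()), "n": n}


def run_monotonicity(seed: int = 0, levels=(1.0, 2.0, 4.0, 8.0, 16.0), n: int = 50) -> dict:
    """Per-stiffness-level feature means plus adjacent-level Welch p-values."""
    from scipy import stats

    from . import features as feat
    from .synthetic import ChannelGeometry, ClassConfig, PopulationConfig, sample_population, simulate_transit

    geom = ChannelGeometry()
    samples = {}
    for s in levels:
        pop = PopulationConfig(
            classes=(
                ClassConfig(name="a", n=n, diameter_mean=14.0, diameter_sd=1.0,
                            stiffness_mean=s, stiffness_sd=0.1 * s),
                ClassConfig(name="b", n=1, stiffness_mean=1.0),
            ),
            seed=seed,
        )
        di, tt, vm = [], [], []
        for c in sample_population(pop):
            if c.class_label != "a":
                continue
            tr = simulate_transit(c, geom)
            di.append(tr.max_di)
            tt.append(feat.compute_transition_time(tr))
            vm.append(feat.compute_vmax(tr, geom.flow_velocity))
        samples[s] = {"di": np.asarray(di), "tt": np.asarray(tt), "vmax": np.asarray(vm)}
    means = {k: [float(samples[s][k].mean()) for s in levels] for k in ("di", "tt", "vmax")}
    pvals = {
        k: [
            float(stats.ttest_ind(samples[a][k], samples[b][k], equal_var=False).pvalue)
            for a, b in zip(levels, levels[1:])
        ]
        for k in ("di", "tt", "vmax")
    }
    return {"levels": list(levels), "means": means, "pvalues": pvals, "n_per_level": n}


def run_gradcam_localization(out_dir: str | Path, seed: int = 0, n_images: int = 50,
                             n_per_class: int = 150, epochs: int = 5) -> dict:
    """Train the image classifier on a visually separable population, then
    measure for how many test images the Grad-CAM heat concentrates inside
    the (generator-known) cell mask."""
    from .evaluation import grad_cam

    config = RunConfig(seed=seed, epochs=epochs, k_folds=4)
    pop = no_harm_population(n_per_class, seed=seed)
    _, sets, _, _ = prepare_benchmark_sets(pop, out_dir, config,
                                           frames=("entry", "squeezed"))
    enc, rep = _train_eval_cnn(sets, config, seed=seed)
    test = sets["test"]
    n_images = min(n_images, len(test))
    hits = 0
    for i in range(n_images):
        img = test.images[i]
        cam = grad_cam(enc, img, layer="last")
        mask = img[0] > 0.35  # cells render brighter than the 0.12 background
        if mask.sum() == 0 or mask.all():
            continue
        if cam[mask].mean() > cam[~mask].mean():
            hits += 1
    return {
        "fraction_localized": hits / n_images,
        "n_images": n_images,
        "cnn_test_accuracy": rep["test"]["per_cell"]["accuracy"],
    }
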