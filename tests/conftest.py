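import numpy as np
import pytest

from miml import features as feat
from miml import synthetic as syn
from miml.fusion import ExampleSet


@pytest.fixture(scope="session")
def geometry():
    return syn.ChannelGeometry()


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """A small on-disk dataset (20 cells, 64x64 frames) shared across tests."""
    out = tmp_path_factory.mktemp("dataset")
    pop = syn.default_population(n_per_class=10, texture_overlap=0.5, seed=11)
    summary = syn.make_dataset(pop, out_dir=out)
    return out, summary


def make_memory_examples(
    n_per_class=20,
    overlap=1.0,
    stiffness=(4.0, 6.8),
    diameter=(14.0, 1.2),
    image_size=32,
    pixel_scale=1.4,
    frames=("entry",),
    features=("di", "tt", "vmax"),
    seed=0,
):
    """Build an in-memory ExampleSet straight from the simulator (no files).

    Mechanical features are min-max normalized over the generated set itself;
    intended for small unit-test datasets only.
    """
    geom = syn.ChannelGeometry()
    spec = syn.ImageSpec(height=image_size, width=image_size, pixel_scale=pixel_scale)
    classes = tuple(
        syn.ClassConfig(
            name=name, n=n_per_class, diameter_mean=diameter[0], diameter_sd=diameter[1],
            stiffness_mean=s, stiffness_sd=0.25 * s,
            texture_sigma=sig, texture_amp=amp, brightness=br,
        )
        for name, s, sig, amp, br in (
            ("soft", stiffness[0], 3.0, 0.10, 0.80),
            ("stiff", stiffness[1], 1.0, 0.22, 0.62),
        )
    )
    pop = syn.PopulationConfig(classes=classes, texture_overlap=overlap, seed=seed)
    cells = syn.sample_population(pop)
    raw = {f: [] for f in features}
    images, labels, cell_ids = [], [], []
    label_of = {"soft": 0, "stiff": 1}
    for cell in cells:
        trace = syn.simulate_transit(cell, geom)
        sq = trace.squeezed_step()
        vals = {
            "di": feat.compute_di(float(trace.major_axis[sq]), float(trace.minor_axis[sq])),
            "tt": feat.compute_transition_time(trace),
            "vmax": feat.compute_vmax(trace, geom.flow_velocity),
            "dir": feat.compute_dir(trace.di_series, trace.dt),
        }
        for f in features:
            raw[f].append(vals[f])
        cell_frames = []
        for which in frames:
            seq = syn.render_frames(trace, cell, which=which, spec=spec, seed=seed)
            cell_frames.append(seq.frames[0][None, :, :])
        images.append(cell_frames)
        labels.append(label_of[cell.class_label])
        cell_ids.append(cell.cell_id)
    norm = {}
    for f in features:
        v = np.asarray(raw[f])
        if f == "di":
            norm[f] = np.clip(v, 0, 1)
        else:
            lo, hi = v.min(), v.max()
            norm[f] = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    mech = np.column_stack([norm[f] for f in features])
    all_images, all_mech, all_labels, all_ids = [], [], [], []
    for i in range(len(cells)):
        for frame_img in images[i]:
            all_images.append(frame_img)
            all_mech.append(mech[i])
            all_labels.append(labels[i])
            all_ids.append(cell_ids[i])
    return ExampleSet(
        images=np.stack(all_images),
        mech=np.stack(all_mech),
        labels=np.asarray(all_labels),
        cell_ids=all_ids,
    )


def split_examples(data: ExampleSet, val_fraction=0.3, seed=0):
    """Grouped (by cell) train/val split of an ExampleSet."""
    rng = np.random.default_rng(seed)
    cells = sorted(set(data.cell_ids))
    cells = [cells[i] for i in rng.permutation(len(cells))]
    n_val = max(1, int(round(val_fraction * len(cells))))
    val_cells = set(cells[:n_val])
    val_idx = np.array([i for i, c in enumerate(data.cell_ids) if c in val_cells])
    train_idx = np.array([i for i, c in enumerate(data.cell_ids) if c not in val_cells])
    return data.subset(train_idx), data.subset(val_idx)


@pytest.fixture(scope="session")
def tiny_mech_separable():
    """Mechanics-separable, visually uninformative examples (32x32)."""
    return make_memory_examples(n_per_class=20, overlap=1.0, stiffness=(2.0, 9.0), seed=7)
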