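"""Synthetic constriction-transit data: cell populations, transit mechanics,
and rendered grayscale frames.

Two cell populations differing in stiffness are pushed through a virtual
constriction channel. A phenomenological mechanics model produces, per cell,
a time series of shape (major/minor axes) and centroid position from which
the biomechanical features (deformation index, transition time, normalized
maximum velocity, deformation-index rate) are computed. A renderer turns
trace steps into grayscale frames: an anti-aliased ellipse with
class-dependent interior texture whose separability is controlled by a
single overlap knob (1.0 = classes visually indistinguishable).

Mechanics model
---------------
For a cell of diameter ``D`` and stiffness ``s`` in a channel of gap ``g``
(with ``D > g``):

* effective compressed gap  ``g_eff = g + (D - g) * s / (s + s0)``
* the minor axis relaxes exponentially toward ``g_eff`` inside the
  constriction (rate proportional to ``1/s``) and back toward ``D`` after exit
* the major axis follows 2-D area conservation, ``a = D**2 / b``
* transit velocity inside the constriction is
  ``u_flow / (1 + kappa * s * (D - g) / g)``

Cells no wider than the gap advect freely and stay circular. The model is
deliberately minimal: soft cells deform more, transit faster, and recover
faster than stiff cells, and each of those orderings is monotone in ``s``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ChannelGeometry",
    "CellSpec",
    "ClassConfig",
    "PopulationConfig",
    "TransitTrace",
    "FrameSequence",
    "ImageSpec",
    "ConfigurationError",
    "RenderError",
    "sample_population",
    "simulate_transit",
    "render_frames",
    "make_dataset",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "cell_id",
    "class",
    "di",
    "tt_ms",
    "vmax_norm",
    "dir_per_ms",
    "img_entry",
    "img_squeezed",
]


class ConfigurationError(ValueError):
    """Invalid population or geometry configuration."""


class RenderError(ValueError):
    """A frame could not be rendered (e.g. the cell exceeds frame bounds)."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Constriction channel geometry (lengths in µm, velocity in µm/ms)."""

    gap: float = 5.2
    depth: float = 20.0
    constriction_length: float = 30.0
    channel_length: float = 120.0
    flow_velocity: float = 1.0

    def __post_init__(self):
        if self.gap <= 0 or self.constriction_length <= 0:
            raise ConfigurationError("gap and constriction_length must be positive")
        if self.flow_velocity <= 0:
            raise ConfigurationError("flow_velocity must be positive")


@dataclass(frozen=True)
class CellSpec:
    """Latent ground truth for one simulated cell."""

    cell_id: str
    class_label: str
    diameter: float  # µm
    stiffness: float  # dimensionless stretching resistance (Ks analog)
    bending: float = 0.0  # Kb analog; reserved, unused by the 2-D model
    texture_seed: int = 0
    # rendering appearance (resolved from class + overlap at sampling time)
    texture_sigma: float = 2.0  # spatial scale of interior texture, px
    texture_amp: float = 0.15
    brightness: float = 0.75

    def __post_init__(self):
        if self.diameter <= 0:
            raise ConfigurationError(f"diameter must be > 0, got {self.diameter}")
        if self.stiffness <= 0:
            raise ConfigurationError(f"stiffness must be > 0, got {self.stiffness}")


@dataclass(frozen=True)
class ClassConfig:
    """Sampling distribution for one cell population.

    Default diameters follow the two measured populations (14.2 ± 4.4 µm and
    13.5 ± 1.5 µm); texture parameters set the class's visual appearance
    before the overlap knob mixes the two classes together.
    """

    name: str
    n: int
    diameter_mean: float = 14.2
    diameter_sd: float = 4.4
    stiffness_mean: float = 2.0
    stiffness_sd: float = 0.4
    texture_sigma: float = 2.0
    texture_amp: float = 0.15
    brightness: float = 0.75

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError(f"class '{self.name}': count must be >= 1")
        if self.diameter_sd < 0 or self.stiffness_sd < 0:
            raise ConfigurationError(f"class '{self.name}': sds must be >= 0")
        if self.diameter_mean <= 0 or self.stiffness_mean <= 0:
            raise ConfigurationError(f"class '{self.name}': means must be > 0")


@dataclass(frozen=True)
class PopulationConfig:
    classes: tuple[ClassConfig, ClassConfig]
    texture_overlap: float = 1.0  # 1 = classes visually indistinguishable
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.texture_overlap <= 1.0:
            raise ConfigurationError("texture_overlap must be in [0, 1]")
        if len({c.name for c in self.classes}) != len(self.classes):
            raise ConfigurationError("class names must be unique")


def default_population(
    n_per_class: int = 100,
    texture_overlap: float = 1.0,
    stiffness_soft: float = 2.0,
    stiffness_stiff: float = 8.0,
    stiffness_sd_frac: float = 0.2,
    diameter_sd: float = 1.3,
    seed: int = 0,
) -> PopulationConfig:
    """Convenience two-class population: a soft tumor-like class vs a stiffer
    blood-cell-like class. Diameter sds default to a render-safe desk scale;
    pass ``diameter_sd=None`` to keep the measured per-class defaults."""
    soft = ClassConfig(
        name="soft",
        n=n_per_class,
        diameter_mean=14.2,
        diameter_sd=4.4 if diameter_sd is None else diameter_sd,
        stiffness_mean=stiffness_soft,
        stiffness_sd=stiffness_soft * stiffness_sd_frac,
        texture_sigma=3.0,
        texture_amp=0.10,
        brightness=0.80,
    )
    stiff = ClassConfig(
        name="stiff",
        n=n_per_class,
        diameter_mean=13.5,
        diameter_sd=1.5 if diameter_sd is None else diameter_sd,
        stiffness_mean=stiffness_stiff,
        stiffness_sd=stiffness_stiff * stiffness_sd_frac,
        texture_sigma=1.0,
        texture_amp=0.22,
        brightness=0.62,
    )
    return PopulationConfig(classes=(soft, stiff), texture_overlap=texture_overlap, seed=seed)


@dataclass
class TransitTrace:
    """Time series of one cell's passage through the channel.

    ``entry_index``/``exit_index`` are the first steps at which the centroid
    crosses the constriction entry (x=0) and exit (x=constriction_length)
    planes; ``exit_index`` is ``None`` for an incomplete transit. The trace
    continues past the exit plane so shape recovery is recorded.
    """

    dt: float  # ms
    times: np.ndarray  # ms
    centroid_x: np.ndarray  # µm
    major_axis: np.ndarray  # a, µm
    minor_axis: np.ndarray  # b, µm
    velocity: np.ndarray  # µm/ms
    entry_index: int | None
    exit_index: int | None

    @property
    def di_series(self) -> np.ndarray:
        a, b = self.major_axis, self.minor_axis
        return (a - b) / (a + b)

    @property
    def max_di(self) -> float:
        return float(self.di_series.max())

    def squeezed_step(self) -> int:
        """Step of maximal deformation (the 'termination of squeezing' frame)."""
        return int(np.argmax(self.di_series))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled normal, truncated to [lo, hi]."""
    if sd == 0:
        val = min(max(mean, lo), hi)
        return np.full(n, val)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def sample_population(config: PopulationConfig, seed: int | None = None) -> list[CellSpec]:
    """Draw cell specs for every class in ``config``.

    Deterministic given the seed. Diameters are truncated to the render-safe
    interval [max(0.5, mean - 3 sd), mean + 3 sd]; stiffness is truncated
    below at 0.05.
    """
    seed = config.seed if seed is None else seed
    ov = config.texture_overlap
    # appearance midpoint used to interpolate classes toward indistinguishable
    mid_sigma = float(np.mean([c.texture_sigma for c in config.classes]))
    mid_amp = float(np.mean([c.texture_amp for c in config.classes]))
    mid_bright = float(np.mean([c.brightness for c in config.classes]))
    cells: list[CellSpec] = []
    for ci, cls in enumerate(config.classes):
        rng = np.random.default_rng([seed, ci])
        lo = max(0.5, cls.diameter_mean - 3 * cls.diameter_sd)
        hi = cls.diameter_mean + 3 * cls.diameter_sd
        diameters = _truncated_normal(rng, cls.diameter_mean, cls.diameter_sd, lo, hi, cls.n)
        stiff = _truncated_normal(rng, cls.stiffness_mean, cls.stiffness_sd, 0.05, np.inf, cls.n)
        tex_seeds = rng.integers(0, 2**31 - 1, size=cls.n)
        for j in range(cls.n):
            cells.append(
                CellSpec(
                    cell_id=f"{cls.name}_{j:05d}",
                    class_label=cls.name,
                    diameter=float(diameters[j]),
                    stiffness=float(stiff[j]),
                    texture_seed=int(tex_seeds[j]),
                    texture_sigma=cls.texture_sigma * (1 - ov) + mid_sigma * ov,
                    texture_amp=cls.texture_amp * (1 - ov) + mid_amp * ov,
                    brightness=cls.brightness * (1 - ov) + mid_bright * ov,
                )
            )
    return cells


# mechanics-model constants (see module docstring)
STIFFNESS_SCALE_S0 = 5.0
FRICTION_KAPPA = 0.1
RELAXATION_RATE_R0 = 1.0  # 1/ms at unit stiffness


def effective_gap(diameter: float, stiffness: float, gap: float, s0: float = STIFFNESS_SCALE_S0) -> float:
    """Closed-form compressed minor-axis target g_eff (µm)."""
    if diameter <= gap:
        return diameter
    return gap + (diameter - gap) * stiffness / (stiffness + s0)


def transit_velocity(
    diameter: float, stiffness: float, geom: ChannelGeometry, kappa: float = FRICTION_KAPPA
) -> float:
    """Constant in-constriction velocity (µm/ms)."""
    if diameter <= geom.gap:
        return geom.flow_velocity
    friction = kappa * stiffness * (diameter - geom.gap) / geom.gap
    return geom.flow_velocity / (1.0 + friction)


def simulate_transit(
    cell: CellSpec,
    geom: ChannelGeometry,
    dt: float = 0.5,
    lead: float = 4.0,
    tail: float = 15.0,
    max_steps: int = 200_000,
) -> TransitTrace:
    """Integrate the phenomenological transit model.

    The centroid starts ``lead`` µm before the entry plane and the trace runs
    until ``tail`` µm past the exit plane so that post-constriction shape
    recovery is captured (needed for the deformation-index rate).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    d, s = cell.diameter, cell.stiffness
    g_eff = effective_gap(d, s, geom.gap)
    v_in = transit_velocity(d, s, geom)
    rate = RELAXATION_RATE_R0 / s
    l_c = geom.constriction_length
    x = -abs(lead)
    b = d
    xs, bs, vs = [], [], []
    for _ in range(max_steps):
        inside = 0.0 <= x < l_c
        v = v_in if inside else geom.flow_velocity
        xs.append(x)
        bs.append(b)
        vs.append(v)
        if x >= l_c + tail:
            break
        target = g_eff if inside else d
        # exact exponential step toward the target (unconditionally stable)
        b = target + (b - target) * math.exp(-rate * dt)
        x += v * dt
    else:
        raise RuntimeError("transit did not complete within max_steps")
    xs = np.asarray(xs)
    bs = np.asarray(bs)
    vs = np.asarray(vs)
    entry = np.nonzero(xs >= 0.0)[0]
    exit_ = np.nonzero(xs >= l_c)[0]
    return TransitTrace(
        dt=dt,
        times=np.arange(len(xs)) * dt,
        centroid_x=xs,
        major_axis=d * d / bs,
        minor_axis=bs,
        velocity=vs,
        entry_index=int(entry[0]) if entry.size else None,
        exit_index=int(exit_[0]) if exit_.size else None,
    )


@dataclass(frozen=True)
class ImageSpec:
    height: int = 64
    width: int = 64
    pixel_scale: float = 0.8  # µm per pixel
    background: float = 0.12
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ConfigurationError("frames must be at least 8x8")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")


@dataclass
class FrameSequence:
    frames: list[np.ndarray]  # each (H, W) float in [0, 1]
    pixel_scale: float
    frame_indices: list[int]  # indices into the source TransitTrace


def _render_frame(
    a: float,
    b: float,
    cell: CellSpec,
    spec: ImageSpec,
    rng: np.random.Generator,
    frame_label: str,
) -> np.ndarray:
    h, w = spec.height, spec.width
    ra = a / 2.0 / spec.pixel_scale  # semi-axes in pixels
    rb = b / 2.0 / spec.pixel_scale
    if 2 * ra > w - 2 or 2 * rb > h - 2:
        raise RenderError(
            f"frame '{frame_label}' of cell {cell.cell_id}: ellipse "
            f"{2 * ra:.1f}x{2 * rb:.1f} px exceeds {w}x{h} frame"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r = np.sqrt(((xx - cx) / ra) ** 2 + ((yy - cy) / rb) ** 2)
    # ~1 px anti-aliased edge in the normalized radial coordinate
    edge = 1.0 / min(ra, rb)
    coverage = np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=cell.texture_sigma)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    img = np.full((h, w), spec.background)
    img += coverage * (cell.brightness - spec.background)
    img += coverage * cell.texture_amp * texture
    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    return np.clip(img, 0.0, 1.0)


def render_frames(
    trace: TransitTrace,
    cell: CellSpec,
    which: str = "all",
    spec: ImageSpec | None = None,
    seed: int = 0,
) -> FrameSequence:
    """Render grayscale frames from a transit trace.

    ``which`` selects 'entry' (frame at the entry plane), 'squeezed' (frame of
    maximal deformation) or 'all'. The frame window follows the cell, so the
    ellipse is always drawn centred. Deterministic given (cell, seed).
    """
    spec = spec or ImageSpec()
    if which == "entry":
        if trace.entry_index is None:
            raise ValueError(f"cell {cell.cell_id}: trace never reaches the entry plane")
        indices = [trace.entry_index]
    elif which == "squeezed":
        indices = [trace.squeezed_step()]
    elif which == "all":
        indices = list(range(len(trace.times)))
    else:
        raise ValueError(f"which must be 'entry', 'squeezed' or 'all', got {which!r}")
    frames = []
    for idx in indices:
        rng = np.random.default_rng([seed, cell.texture_seed, idx])
        frames.append(
            _render_frame(
                float(trace.major_axis[idx]),
                float(trace.minor_axis[idx]),
                cell,
                spec,
                rng,
                frame_label=f"{which}[{idx}]",
            )
        )
    return FrameSequence(frames=frames, pixel_scale=spec.pixel_scale, frame_indices=indices)


def _save_png(img: np.ndarray, path: Path) -> None:
    Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8), mode="L").save(path)


def make_dataset(
    pop: PopulationConfig,
    geom: ChannelGeometry | None = None,
    image_spec: ImageSpec | None = None,
    out_dir: str | Path = ".",
    dt: float = 0.5,
) -> dict:
    """Simulate a full population and write images + manifest CSV to disk.

    One row per cell with ground-truth features computed from its trace, and
    two PNG frames ('entry' and 'squeezed') per cell. Returns a summary with
    per-class counts and the manifest path.
    """
    from . import features  # local import to avoid a cycle

    geom = geom or ChannelGeometry()
    image_spec = image_spec or ImageSpec()
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    cells = sample_population(pop)
    rows = []
    counts: dict[str, int] = {}
    for cell in cells:
        trace = simulate_transit(cell, geom, dt=dt)
        if trace.exit_index is None:
            raise RuntimeError(f"cell {cell.cell_id}: incomplete transit")
        sq = trace.squeezed_step()
        di = features.compute_di(float(trace.major_axis[sq]), float(trace.minor_axis[sq]))
        tt = features.compute_transition_time(trace)
        vmax = features.compute_vmax(trace, geom.flow_velocity)
        dir_ = features.compute_dir(trace.di_series, dt)
        seq = render_frames(trace, cell, which="entry", spec=image_spec, seed=pop.seed)
        entry_img = seq.frames[0]
        seq = render_frames(trace, cell, which="squeezed", spec=image_spec, seed=pop.seed)
        squeezed_img = seq.frames[0]
        p_entry = img_dir / f"{cell.cell_id}_entry.png"
        p_squeezed = img_dir / f"{cell.cell_id}_squeezed.png"
        try:
            _save_png(entry_img, p_entry)
            _save_png(squeezed_img, p_squeezed)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed to write image under {img_dir}: {exc}") from exc
        rows.append(
            {
                "cell_id": cell.cell_id,
                "class": cell.class_label,
                "di": f"{di:.17g}",
                "tt_ms": f"{tt:.17g}",
                "vmax_norm": f"{vmax:.17g}",
                "dir_per_ms": f"{dir_:.17g}",
                "img_entry": str(p_entry.relative_to(out_dir)),
                "img_squeezed": str(p_squeezed.relative_to(out_dir)),
            }
        )
        counts[cell.class_label] = counts.get(cell.class_label, 0) + 1
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return {"manifest": str(manifest_path), "counts": counts, "n_cells": len(rows)}
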