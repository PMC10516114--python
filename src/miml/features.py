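"""Biomechanical feature extraction.

Computes the per-cell mechanical feature vector m = (DI, TT, vmax[, DIR]):

* DI  — deformation index (a - b) / (a + b) from the fitted cell ellipse
* TT  — transition time between the constriction entry and exit planes
* vmax — peak centroid velocity inside the constriction, normalized by the
  imposed flow velocity
* DIR — mean absolute rate of change of DI over the squeeze-and-recover
  window (the signed rate averages to ~0 over a symmetric cycle, so the
  absolute value is used)

plus image segmentation (Otsu threshold, morphological closing, largest
connected component — a lightweight stand-in for a trained detector),
moment-based ellipse fitting, and train-split-only min-max normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .synthetic import TransitTrace

__all__ = [
    "SegmentationMask",
    "EllipseFit",
    "MechanicalFeatures",
    "NoCellError",
    "segment_cell",
    "fit_ellipse",
    "compute_di",
    "compute_transition_time",
    "compute_vmax",
    "compute_dir",
    "MinMaxNormalizer",
    "extract_from_images",
]


class NoCellError(ValueError):
    """Segmentation found no foreground object."""


@dataclass
class SegmentationMask:
    mask: np.ndarray  # bool (H, W)
    component_count: int  # foreground components before the largest-only filter


@dataclass
class EllipseFit:
    a: float  # major axis (full length)
    b: float  # minor axis (full length)
    centroid: tuple[float, float]  # (x, y)
    orientation: float  # radians

    def __post_init__(self):
        if not self.a >= self.b > 0:
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")


@dataclass
class MechanicalFeatures:
    di: float
    tt: float  # ms, raw
    vmax: float  # normalized by flow velocity
    dir: float | None = None  # 1/ms

    @property
    def d(self) -> int:
        return 3 if self.dir is None else 4

    def as_vector(self) -> np.ndarray:
        vals = [self.di, self.tt, self.vmax]
        if self.dir is not None:
            vals.append(self.dir)
        return np.asarray(vals, dtype=float)


def segment_cell(image: np.ndarray, closing_radius: int = 2) -> SegmentationMask:
    """Global Otsu threshold -> morphological closing -> largest component."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.max() - image.min() < 1e-6:
        raise NoCellError("no cell detected: image has no contrast")
    thr = threshold_otsu(image)
    fg = image > thr
    if closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(closing_radius))
    labels, n = measure.label(fg, return_num=True)
    if n == 0:
        raise NoCellError("no cell detected: empty foreground after thresholding")
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    return SegmentationMask(mask=labels == keep, component_count=n)


def fit_ellipse(mask: SegmentationMask, pixel_scale: float = 1.0) -> EllipseFit:
    """Fit an ellipse from second-order image moments of the mask.

    Axis lengths are scaled to µm with ``pixel_scale``; a >= b is enforced by
    the eigenvalue ordering of the moment tensor.
    """
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    props = measure.regionprops(m.astype(np.uint8))
    if not props:
        raise NoCellError("no cell detected: empty mask")
    p = props[0]
    a_px = p.axis_major_length
    b_px = p.axis_minor_length
    if b_px < 2.0:
        raise ValueError(f"component thinner than 2 px (minor axis {b_px:.2f} px): axes unresolvable")
    cy, cx = p.centroid
    return EllipseFit(
        a=a_px * pixel_scale,
        b=b_px * pixel_scale,
        centroid=(cx, cy),
        orientation=float(p.orientation),
    )


def compute_di(a: float, b: float) -> float:
    """Deformation index (a - b) / (a + b); 0 for a circle, -> 1 as b -> 0."""
    if a < b:
        a, b = b, a
    if a + b == 0:
        raise ValueError("deformation index undefined for a + b = 0")
    if b < 0:
        raise ValueError("axes must be non-negative")
    return (a - b) / (a + b)


def compute_transition_time(trace: TransitTrace) -> float:
    """(exit_index - entry_index) * dt, in ms."""
    if trace.entry_index is None or trace.exit_index is None:
        raise ValueError("incomplete transit: cell never exits the constriction")
    if not trace.entry_index < trace.exit_index:
        raise ValueError("incomplete transit: entry_index must precede exit_index")
    return (trace.exit_index - trace.entry_index) * trace.dt


def compute_vmax(trace: TransitTrace, u_flow: float) -> float:
    """Peak centroid displacement rate within [entry, exit], / u_flow."""
    if u_flow <= 0:
        raise ValueError(f"u_flow must be positive, got {u_flow}")
    if trace.entry_index is None or trace.exit_index is None:
        raise ValueError("incomplete transit: cell never exits the constriction")
    lo, hi = trace.entry_index, trace.exit_index
    x = trace.centroid_x[lo : hi + 1]
    if x.size < 2:
        raise ValueError("transit window too short to estimate velocity")
    rates = np.diff(x) / trace.dt
    return float(rates.max() / u_flow)


def compute_dir(di_series: np.ndarray, dt: float, window: slice | None = None) -> float:
    """Mean |ΔDI| / dt over the squeeze-and-recover window (default: full series)."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    s = np.asarray(di_series, dtype=float)
    if window is not None:
        s = s[window]
    if s.size < 2:
        raise ValueError("need at least 2 samples to compute a rate")
    return float(np.abs(np.diff(s)).mean() / dt)


class MinMaxNormalizer:
    """Map values to [0, 1] with bounds fixed on the training split.

    With explicit ``bounds`` the mapping is (x - lo) / (hi - lo) clipped to
    [0, 1]; otherwise ``fit`` records min/max of the training values and
    ``transform`` reuses them (out-of-range test values clip).
    """

    def __init__(self, bounds: tuple[float, float] | None = None):
        if bounds is not None and not bounds[1] > bounds[0]:
            raise ValueError(f"require hi > lo, got bounds={bounds}")
        self.lo, self.hi = bounds if bounds is not None else (None, None)

    @property
    def fitted(self) -> bool:
        return self.lo is not None

    def fit(self, values: np.ndarray) -> "MinMaxNormalizer":
        v = np.asarray(values, dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            warnings.warn("constant feature: normalizing to all zeros", stacklevel=2)
            hi = lo + 1.0
        self.lo, self.hi = lo, hi
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer not fitted and no bounds given")
        v = np.asarray(values, dtype=float)
        return np.clip((v - self.lo) / (self.hi - self.lo), 0.0, 1.0)

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


def extract_from_images(
    entry_image: np.ndarray,
    squeezed_image: np.ndarray,
    pixel_scale: float = 1.0,
) -> float:
    """Image-route DI: segment the squeezed frame, fit an ellipse, return DI.

    Provided as the image-only counterpart to the trace-route features; used
    by the extract CLI and by round-trip checks.
    """
    mask = segment_cell(np.asarray(squeezed_image))
    fit = fit_ellipse(mask, pixel_scale=pixel_scale)
    return compute_di(fit.a, fit.b)
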