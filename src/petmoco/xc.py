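"""Masked normalized cross-correlation image-quality evaluation.

Image similarity over time is measured as the zero-mean (Pearson-form)
3-D normalized cross-correlation (XC) between each evaluation frame and
the reference frame, restricted to a brain mask.  The mask is built by
Gaussian-filtering the reference (default 16 mm FWHM) and keeping voxels
at or above 30% of the filtered maximum; both volumes are filtered with a
3 mm FWHM Gaussian before the correlation.  XC is 1 for identical volumes
(up to any affine intensity change) and 0 for uncorrelated ones.

Gaussian widths are FWHM in mm (sigma = FWHM / 2.3548); filtering uses a
truncated kernel (radius 4 sigma) renormalised at the volume edges so
border voxels are not biased toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import DynamicSeries
from .geometry import InvalidInputError, VolumeGrid

DEFAULT_MASK_FWHM_MM = 16.0
DEFAULT_MASK_THRESHOLD_FRAC = 0.30
DEFAULT_XC_FWHM_MM = 3.0

_FWHM_TO_SIGMA = 1.0 / 2.3548


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: one of the volumes has zero variance in the mask."""


def smooth_fwhm(values: np.ndarray, fwhm_mm: float, spacing) -> np.ndarray:
    """Gaussian filter with edge-renormalised truncated kernel (radius 4 sigma)."""
    if not fwhm_mm or fwhm_mm <= 0:
        return np.asarray(values, dtype=float)
    sigma = fwhm_mm * _FWHM_TO_SIGMA / np.asarray(spacing, dtype=float)
    num = ndimage.gaussian_filter(np.asarray(values, dtype=float), sigma,
                                  mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(np.ones(values.shape), sigma,
                                  mode="constant", truncate=4.0)
    return num / den


@dataclass
class BrainMask:
    """Boolean brain mask with the parameters that generated it."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    smooth_fwhm_mm: float
    threshold_frac: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.mask.ndim != 3 or not self.mask.any():
            raise InvalidInputError("mask must be 3-D and nonempty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def aligned_with(self, v: VolumeGrid) -> bool:
        return (
            self.mask.shape == v.shape
            and np.array_equal(self.spacing, v.spacing)
            and np.array_equal(self.origin, v.origin)
        )


def make_brain_mask(
    reference: VolumeGrid,
    smooth_fwhm_mm: float = DEFAULT_MASK_FWHM_MM,
    threshold_frac: float = DEFAULT_MASK_THRESHOLD_FRAC,
) -> BrainMask:
    """Threshold the Gaussian-filtered reference at a fraction of its maximum.

    Voxels whose *filtered* value is >= ``threshold_frac`` times the
    filtered maximum are included.
    """
    if reference.values.max() <= 0:
        raise InvalidInputError("reference must have a positive maximum")
    sm = smooth_fwhm(reference.values, smooth_fwhm_mm, reference.spacing)
    mask = sm >= threshold_frac * sm.max()
    return BrainMask(mask, reference.spacing.copy(), reference.origin.copy(),
                     float(smooth_fwhm_mm), float(threshold_frac))


def xc(
    frame: VolumeGrid,
    reference: VolumeGrid,
    mask: BrainMask,
    smooth_fwhm_mm: float = DEFAULT_XC_FWHM_MM,
) -> float:
    """Zero-mean normalized cross-correlation of two volumes within the mask.

    Both volumes are Gaussian-filtered (``smooth_fwhm_mm``) over the full
    grid, then the Pearson-form correlation
    ``sum((a - a̅)(b - b̅)) / sqrt(sum((a - a̅)²) · sum((b - b̅)²))``
    is taken over mask voxels.
    """
    if not frame.aligned_with(reference):
        raise InvalidInputError("frame and reference grids are not aligned")
    if not mask.aligned_with(reference):
        raise InvalidInputError("mask is not aligned with the reference grid")
    a = smooth_fwhm(frame.values, smooth_fwhm_mm, frame.spacing)[mask.mask]
    b = smooth_fwhm(reference.values, smooth_fwhm_mm, reference.spacing)[mask.mask]
    a = a - a.mean()
    b = b - b.mean()
    va, vb = float(a @ a), float(b @ b)
    if va == 0.0 or vb == 0.0:
        raise UndefinedCorrelationError("zero variance within the mask")
    return float(np.clip((a @ b) / np.sqrt(va * vb), -1.0, 1.0))


@dataclass
class XCSeries:
    """Per-frame XC against the reference frame."""

    values: np.ndarray
    start_s: np.ndarray
    duration_s: np.ndarray
    reference_index: int
    smooth_fwhm_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        self.start_s = np.asarray(self.start_s, dtype=float).reshape(-1)
        self.duration_s = np.asarray(self.duration_s, dtype=float).reshape(-1)


def xc_series(
    series: DynamicSeries,
    reference_index: int,
    mask: BrainMask,
    smooth_fwhm_mm: float = DEFAULT_XC_FWHM_MM,
) -> XCSeries:
    """XC of every frame against the reference frame."""
    if not 0 <= reference_index < series.n_frames:
        raise InvalidInputError(f"reference_index {reference_index} out of range")
    ref = series.frame(reference_index)
    vals = np.empty(series.n_frames)
    for f in range(series.n_frames):
        try:
            vals[f] = xc(series.frame(f), ref, mask, smooth_fwhm_mm)
        except UndefinedCorrelationError as e:
            raise UndefinedCorrelationError(f"frame {f}: {e}") from e
    return XCSeries(vals, series.timing.start_s.copy(),
                    series.timing.duration_s.copy(), reference_index,
                    float(smooth_fwhm_mm))


def median_xc(s: XCSeries, exclude_reference: bool = True) -> float:
    """Median of the per-frame XC values.

    The reference frame is excluded by default since its value is 1 by
    construction.
    """
    vals = s.values
    if exclude_reference:
        vals = np.delete(vals, s.reference_index)
    if vals.size == 0:
        raise InvalidInputError("no usable frames")
    return float(np.median(vals))


def xc_plot(curves: dict[str, XCSeries], path) -> None:
    """XC-vs-time curves (e.g. noMC and ddMC) on one axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    for label, s in curves.items():
        ax.plot(s.start_s + s.duration_s / 2, s.values, label=label, lw=1.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("XC")
    ax.set_ylim(None, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
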