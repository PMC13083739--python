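"""Motion summarisation: probe displacements, categorisation, cDTH.

Head motion over a scan is summarised by tracking two virtual probe
points placed 70 mm anterior and 70 mm posterior of the brain centre
(anterior = +y in RAS).  Each frame's rigid transform moves the probes;
the Euclidean distance from the reference position is the per-frame
absolute displacement.  The per-probe median displacement — the larger of
the two — drives the automatic three-way motion categorisation:

* low:     deciding median < 1 mm
* medium:  1 mm <= deciding median <= 2 mm
* high:    deciding median > 2 mm

Medians exactly at 1 or 2 mm fall in the medium class (closed middle
interval), the only reading consistent with strict outer inequalities.
The cumulative displacement-time histogram (cDTH) reports, per probe,
the fraction of scan time spent at or below each displacement magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import MotionTrajectory
from .geometry import InvalidInputError

DEFAULT_PROBE_OFFSET_MM = 70.0
LOW_BOUNDARY_MM = 1.0
HIGH_BOUNDARY_MM = 2.0

#: anterior direction (+y of RAS)
_ANTERIOR = np.array([0.0, 1.0, 0.0])


@dataclass
class DisplacementSeries:
    """Per-frame absolute displacement (mm) of the two probe points."""

    anterior_mm: np.ndarray
    posterior_mm: np.ndarray
    duration_s: np.ndarray
    offset_mm: float
    brain_center: np.ndarray
    reference_index: int

    def __post_init__(self) -> None:
        self.anterior_mm = np.asarray(self.anterior_mm, dtype=float).reshape(-1)
        self.posterior_mm = np.asarray(self.posterior_mm, dtype=float).reshape(-1)
        self.duration_s = np.asarray(self.duration_s, dtype=float).reshape(-1)
        self.brain_center = np.asarray(self.brain_center, dtype=float).reshape(3)
        n = self.anterior_mm.size
        if not (self.posterior_mm.size == n == self.duration_s.size) or n == 0:
            raise InvalidInputError("displacement series arrays must be equal-length, nonempty")
        if np.any(self.anterior_mm < 0) or np.any(self.posterior_mm < 0):
            raise InvalidInputError("displacements must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.anterior_mm.size

    def point(self, which: str) -> np.ndarray:
        if which == "anterior":
            return self.anterior_mm
        if which == "posterior":
            return self.posterior_mm
        raise InvalidInputError(f"unknown probe point {which!r}")


@dataclass
class MotionCategory:
    label: str                # "low" | "medium" | "high"
    deciding_median_mm: float
    deciding_point: str       # "anterior" | "posterior"
    anterior_median_mm: float
    posterior_median_mm: float


@dataclass
class CDTH:
    """Cumulative displacement-time histogram for both probe points."""

    thresholds_mm: np.ndarray
    anterior_fraction: np.ndarray
    posterior_fraction: np.ndarray
    bin_width_mm: float

    def fraction(self, which: str) -> np.ndarray:
        return self.anterior_fraction if which == "anterior" else self.posterior_fraction


def probe_displacements(
    traj: MotionTrajectory,
    brain_center,
    offset_mm: float = DEFAULT_PROBE_OFFSET_MM,
) -> DisplacementSeries:
    """Displacement series of the anterior/posterior probe points.

    The anterior probe sits at ``brain_center + offset_mm * (+y)``, the
    posterior probe at the mirrored position; per frame, displacement is
    the Euclidean distance between the transformed and original point.
    """
    if traj.n_frames == 0:
        raise InvalidInputError("trajectory is empty")
    center = np.asarray(brain_center, dtype=float).reshape(3)
    pa = center + offset_mm * _ANTERIOR
    pp = center - offset_mm * _ANTERIOR
    ant = np.array([np.linalg.norm(t.apply(pa) - pa) for t in traj.transforms])
    post = np.array([np.linalg.norm(t.apply(pp) - pp) for t in traj.transforms])
    return DisplacementSeries(
        ant, post, traj.timing.duration_s.copy(), float(offset_mm), center,
        traj.reference_index,
    )


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w)
    half = 0.5 * w.sum()
    i = int(np.searchsorted(cum, half))
    if np.isclose(cum[i], half) and i + 1 < x.size:
        return float(0.5 * (x[i] + x[i + 1]))
    return float(x[i])


def categorize(
    d: DisplacementSeries,
    duration_weighted: bool = False,
    low_boundary_mm: float = LOW_BOUNDARY_MM,
    high_boundary_mm: float = HIGH_BOUNDARY_MM,
) -> MotionCategory:
    """Three-way motion category from the larger per-probe median.

    The median is over frames, unweighted by default (motion-estimation
    frames carry near-constant counts, not constant duration); a
    duration-weighted variant is available behind the flag.
    """
    if duration_weighted:
        med_a = _weighted_median(d.anterior_mm, d.duration_s)
        med_p = _weighted_median(d.posterior_mm, d.duration_s)
    else:
        med_a = float(np.median(d.anterior_mm))
        med_p = float(np.median(d.posterior_mm))
    if med_a >= med_p:
        deciding, point = med_a, "anterior"
    else:
        deciding, point = med_p, "posterior"
    if deciding < low_boundary_mm:
        label = "low"
    elif deciding > high_boundary_mm:
        label = "high"
    else:
        label = "medium"
    return MotionCategory(label, deciding, point, med_a, med_p)


def cdth_fraction(d: DisplacementSeries, threshold_mm: float, which: str) -> float:
    """Duration fraction of the scan with displacement <= ``threshold_mm``."""
    disp = d.point(which)
    total = d.duration_s.sum()
    return float(d.duration_s[disp <= threshold_mm].sum() / total)


def cdth(d: DisplacementSeries, bin_width_mm: float = 0.1) -> CDTH:
    """Cumulative displacement-time histogram.

    Thresholds run from 0 to the maximum displacement rounded up to the
    bin width; fractions are duration-weighted and use non-strict ``<=``.
    """
    if bin_width_mm <= 0:
        raise InvalidInputError("bin_width_mm must be positive")
    dmax = max(d.anterior_mm.max(), d.posterior_mm.max())
    n_bins = int(np.ceil(dmax / bin_width_mm - 1e-12)) if dmax > 0 else 0
    thresholds = bin_width_mm * np.arange(n_bins + 1)
    total = d.duration_s.sum()
    ant = np.array([d.duration_s[d.anterior_mm <= t].sum() for t in thresholds]) / total
    post = np.array([d.duration_s[d.posterior_mm <= t].sum() for t in thresholds]) / total
    return CDTH(thresholds, ant, post, float(bin_width_mm))


def motion_plot(d: DisplacementSeries, path, timing=None) -> None:
    """Displacement-vs-time curves for both probes, reference time marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if timing is not None:
        t = timing.mid_s
    else:
        t = np.concatenate([[0.0], np.cumsum(d.duration_s)[:-1]]) + d.duration_s / 2
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(t, d.anterior_mm, label="anterior", lw=1.5)
    ax.plot(t, d.posterior_mm, label="posterior", lw=1.5)
    ax.axvline(t[d.reference_index], color="k", ls=":", lw=1, label="reference")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("displacement (mm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def cdth_plot(c: CDTH, path) -> None:
    """cDTH step curves for both probes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.step(c.thresholds_mm, c.anterior_fraction, where="post", label="anterior")
    ax.step(c.thresholds_mm, c.posterior_fraction, where="post", label="posterior")
    ax.set_xlabel("displacement (mm)")
    ax.set_ylabel("fraction of scan time ≤ d")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
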