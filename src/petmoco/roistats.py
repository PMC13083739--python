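"""ROI quantification and group statistics.

Computes per-ROI mean signal, relative signal differences between the
motion-corrected and uncorrected static images
(``(ddMC - noMC) / ddMC x 100%``), median/IQR group summaries, exact or
normal-approximation Mann-Whitney U tests with Bonferroni correction, and
the point-displacement registration-QC criterion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import InvalidInputError, VolumeGrid

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FAMILY_SIZE = 11   # number of ROIs in one comparison family
EXACT_MAX_N = 20           # combined sample size for exact enumeration
QC_TOLERANCE_MM = 1.0


@dataclass
class ROITable:
    """Per-ROI mean signal with voxel counts."""

    means: dict[str, float]
    counts: dict[str, int]
    source: str = ""


def roi_means(
    v: VolumeGrid,
    labels: VolumeGrid,
    roi_definitions: dict[str, tuple[int, ...]],
    source: str = "",
) -> ROITable:
    """Arithmetic mean of voxel values per ROI.

    Composite ROIs (whole brain, gray matter, ...) are label unions as
    declared in ``roi_definitions``.
    """
    if not v.aligned_with(labels):
        raise InvalidInputError("value and label grids are not aligned")
    lab = labels.values.astype(int)
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for roi, ids in roi_definitions.items():
        m = np.isin(lab, ids)
        n = int(m.sum())
        if n == 0:
            raise InvalidInputError(f"ROI {roi!r} has no voxels in the label map")
        means[roi] = float(v.values[m].mean())
        counts[roi] = n
    return ROITable(means, counts, source)


@dataclass
class RelDiffTable:
    """Relative signal difference (%) per ROI: (ddMC - noMC) / ddMC x 100."""

    values: dict[str, float]
    missing: tuple[str, ...] = ()


def relative_diff(ddmc: ROITable, nomc: ROITable) -> RelDiffTable:
    """Per-ROI relative signal difference in percent.

    ROIs whose ddMC mean is zero are reported as missing rather than a
    value.
    """
    if set(ddmc.means) != set(nomc.means):
        raise InvalidInputError("ddMC and noMC tables cover different ROI sets")
    values: dict[str, float] = {}
    missing: list[str] = []
    for roi, d in ddmc.means.items():
        if d == 0:
            missing.append(roi)
        else:
            values[roi] = (d - nomc.means[roi]) / d * 100.0
    return RelDiffTable(values, tuple(missing))


@dataclass
class GroupSummary:
    """Median and interquartile range of relative differences per group."""

    # group label -> ROI -> (median, q1, q3), all in percent
    stats: dict[str, dict[str, tuple[float, float, float]]]
    n_scans: dict[str, int] = field(default_factory=dict)


def group_summary(groups: dict[str, list[RelDiffTable]]) -> GroupSummary:
    """Median and [Q1, Q3] per group per ROI (linear-interpolation quartiles).

    Empty groups are omitted with a warning.
    """
    out: dict[str, dict[str, tuple[float, float, float]]] = {}
    n_scans: dict[str, int] = {}
    for label, tables in groups.items():
        if not tables:
            log.warning("group %r is empty; omitted from summary", label)
            continue
        rois = sorted(set().union(*(t.values.keys() for t in tables)))
        per_roi: dict[str, tuple[float, float, float]] = {}
        for roi in rois:
            vals = np.array([t.values[roi] for t in tables if roi in t.values])
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            per_roi[roi] = (float(med), float(q1), float(q3))
        out[label] = per_roi
        n_scans[label] = len(tables)
    return GroupSummary(out, n_scans)


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str          # "exact" | "normal-approx" | "degenerate"
    n_a: int
    n_b: int


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def _exact_mwu(a: np.ndarray, b: np.ndarray) -> MannWhitneyResult:
    """Exact two-sided p by full enumeration of group labelings (midrank ties)."""
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_from_ranks(ranks[:n_a].sum(), n_a)
    n = n_a + n_b
    us = np.fromiter(
        (_u_from_ranks(sum(ranks[i] for i in comb), n_a)
         for comb in itertools.combinations(range(n), n_a)),
        dtype=float,
        count=math.comb(n, n_a),
    )
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return MannWhitneyResult(float(u_obs), float(p), "exact", n_a, n_b)


def mann_whitney_u(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration (midrank ties, two-sided p doubled from
    the smaller tail and capped at 1) for combined n <= 20; normal
    approximation with tie correction and continuity correction beyond.
    If every value in both samples is identical the test is degenerate
    and p = 1.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        u = a.size * b.size / 2.0
        return MannWhitneyResult(u, 1.0, "degenerate", a.size, b.size)
    if a.size + b.size <= EXACT_MAX_N:
        return _exact_mwu(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue),
                             "normal-approx", a.size, b.size)


@dataclass
class TestResult:
    """Per-ROI test outcomes with Bonferroni-adjusted significance flags."""

    results: dict[str, MannWhitneyResult]
    significant: dict[str, bool]
    alpha: float
    m: int


def bonferroni(
    results: dict[str, MannWhitneyResult],
    alpha: float = DEFAULT_ALPHA,
    m: int | None = None,
) -> TestResult:
    """Flag significance at the Bonferroni-adjusted level ``alpha / m``.

    ``m`` defaults to the family size (the number of ROIs tested).
    """
    if m is None:
        m = len(results) if results else DEFAULT_FAMILY_SIZE
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    sig = {roi: r.p < alpha / m for roi, r in results.items()}
    return TestResult(results, sig, alpha, m)


@dataclass
class QCResult:
    passed: bool
    difference_mm: float
    tolerance_mm: float


def registration_qc(disp_a, disp_b, tol_mm: float = QC_TOLERANCE_MM) -> QCResult:
    """Registration check on two displacement vectors of a point source.

    Passes iff the Euclidean norm of the vector difference is <= ``tol_mm``
    (boundary inclusive).
    """
    a = np.asarray(disp_a, dtype=float).reshape(3)
    b = np.asarray(disp_b, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("displacement vectors must be finite")
    mag = float(np.linalg.norm(a - b))
    return QCResult(mag <= tol_mm, mag, float(tol_mm))
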