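"""Synthetic dynamic brain-PET generator.

Provides a procedural 3-D brain-like phantom with an ROI label map
(cortical sectors, cerebellum, subcortical nuclei, white matter,
ventricle-like voids), rigid head-motion trajectories of the archetypes
seen in clinical motion logs (near-static, gradual drift, one-time step,
jitter), and Poisson-noisy dynamic frame series with constant expected
counts per frame.

The phantom is procedural geometry (nested ellipsoids plus a seeded,
smoothly perturbed "folded" cortical shell), not an atlas: it gives the
registration and ROI machinery realistic contrast and structure without
any external data.  Two contrast regimes are provided: ``fdg_like``
(high gray/white contrast, GM/WM mean-activity ratio ~3) and ``met_like``
(amino-acid-tracer-like: globally lower uptake at half the mean activity
and compressed tissue contrast), so that at matched counts the low-uptake
regime yields noisier, lower-contrast frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .correct import correct_series, integrate
from .frames import DynamicSeries, FrameTiming, MotionTrajectory
from .geometry import (
    InvalidInputError,
    RigidTransform,
    VolumeGrid,
    compose,
    invert,
    resample,
)

#: canonical ROI names
ROI_NAMES = ("WB", "CER", "FC", "HIP", "OC", "PC", "STR", "TC", "THA", "GM", "WM")

_LABELS = {1: "FC", 2: "PC", 3: "TC", 4: "OC", 5: "CER", 6: "HIP", 7: "STR", 8: "THA", 9: "WM"}

# tissue activity (relative concentration) in the fdg_like regime
_ACTIVITY = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 0.90, 6: 0.80, 7: 0.95, 8: 0.95, 9: 0.32}
_VENTRICLE_ACTIVITY = 0.08

DEFAULT_COUNTS_PER_FRAME = 5e5


@dataclass
class LabeledPhantom:
    """Brain-like activity map plus aligned integer ROI labels."""

    activity: VolumeGrid
    labels: VolumeGrid
    label_names: dict[int, str]
    roi_definitions: dict[str, tuple[int, ...]]
    brain_center: np.ndarray
    contrast: str = "fdg_like"

    def __post_init__(self) -> None:
        self.brain_center = np.asarray(self.brain_center, dtype=float).reshape(3)
        if not self.activity.aligned_with(self.labels):
            raise InvalidInputError("labels must be aligned with activity")

    def roi_mask(self, roi: str) -> np.ndarray:
        try:
            ids = self.roi_definitions[roi]
        except KeyError:
            raise InvalidInputError(
                f"unknown ROI {roi!r}; known: {sorted(self.roi_definitions)}"
            ) from None
        return np.isin(self.labels.values.astype(int), ids)


def _smooth_noise(rng: np.random.Generator, shape, spacing, fwhm_mm: float) -> np.ndarray:
    """Zero-mean smooth random field, normalised to unit max amplitude."""
    sigma = fwhm_mm / 2.3548 / np.asarray(spacing)
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    n -= n.mean()
    amax = np.abs(n).max()
    return n / amax if amax > 0 else n


def make_phantom(
    shape=(48, 48, 48),
    spacing=3.0,
    contrast: str = "fdg_like",
    seed: int = 0,
) -> LabeledPhantom:
    """Build the procedural labeled brain phantom.

    Parameters
    ----------
    shape : tuple of int
        Grid size; each axis must be >= 32 voxels.
    spacing : float or 3-tuple
        Voxel size in mm.
    contrast : {"fdg_like", "met_like"}
        Tissue-contrast regime (see module docstring).
    seed : int
        Seeds the cortical-fold perturbation and activity texture;
        the phantom is deterministic for a fixed seed.
    """
    shape = tuple(int(n) for n in np.atleast_1d(shape)) if np.ndim(shape) else (int(shape),) * 3
    if len(shape) == 1:
        shape = shape * 3
    if len(shape) != 3 or any(n < 32 for n in shape):
        raise InvalidInputError(f"shape must be >= 32 voxels per axis, got {shape}")
    if contrast not in ("fdg_like", "met_like"):
        raise InvalidInputError(f"unknown contrast regime {contrast!r}")
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    rng = np.random.default_rng(seed)

    origin = np.zeros(3)
    extent = np.asarray(shape) * spacing
    center = origin + (np.asarray(shape) - 1) / 2.0 * spacing
    semi = np.array([0.33, 0.40, 0.30]) * extent  # brain semi-axes, mm

    idx = np.indices(shape, dtype=float)
    world = origin[:, None, None, None] + idx * spacing[:, None, None, None]
    u = (world - center[:, None, None, None]) / semi[:, None, None, None]
    r = np.sqrt((u**2).sum(axis=0))
    brain = r <= 1.0

    # folded cortical shell: seeded smooth perturbation of the inner radius
    fold = _smooth_noise(rng, shape, spacing, fwhm_mm=3.5 * float(spacing.mean()))
    shell_inner = 0.78 + 0.06 * fold
    shell = brain & (r >= shell_inner)
    interior = brain & ~shell

    labels = np.zeros(shape, dtype=int)

    def ellipsoid(offset_mm, semi_mm, mirror_x=False):
        offs = [np.asarray(offset_mm, dtype=float)]
        if mirror_x:
            offs.append(offs[0] * np.array([-1.0, 1.0, 1.0]))
        m = np.zeros(shape, dtype=bool)
        for o in offs:
            c = center + o
            ue = (world - c[:, None, None, None]) / np.asarray(semi_mm)[:, None, None, None]
            m |= (ue**2).sum(axis=0) <= 1.0
        return m

    # cerebellum: posterior-inferior lobe (overrides shell sectors there)
    cer = ellipsoid((0.0, -0.62 * semi[1], -0.72 * semi[2]),
                    (0.45 * semi[0], 0.28 * semi[1], 0.25 * semi[2])) & brain
    labels[cer] = 5

    # cortical sectors by dominant direction
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(r > 0, u / np.maximum(r, 1e-12), 0.0)
    sector = np.where(
        d[1] >= 0.25, 1,                      # frontal
        np.where(d[1] <= -0.25, 4,            # occipital
                 np.where(d[2] >= 0.30, 2, 3))  # parietal else temporal
    )
    cortex = shell & ~cer
    labels[cortex] = sector[cortex]

    free = interior & ~cer
    ventricle = ellipsoid((0.18 * semi[0], 0.05 * semi[1], 0.12 * semi[2]),
                          (0.11 * semi[0], 0.30 * semi[1], 0.18 * semi[2]),
                          mirror_x=True) & free
    for lab, off, sem in (
        (8, (0.22, -0.10, -0.02), (0.16, 0.18, 0.16)),   # thalamus
        (7, (0.36, 0.16, 0.04), (0.15, 0.22, 0.18)),     # striatum
        (6, (0.52, -0.22, -0.30), (0.13, 0.26, 0.15)),   # hippocampus
    ):
        m = ellipsoid(np.asarray(off) * semi, np.asarray(sem) * semi, mirror_x=True)
        m &= free & ~ventricle & (labels == 0)
        labels[m] = lab
    labels[free & ~ventricle & (labels == 0)] = 9  # white matter

    activity = np.zeros(shape, dtype=float)
    for lab, a in _ACTIVITY.items():
        activity[labels == lab] = a
    activity[ventricle] = _VENTRICLE_ACTIVITY
    # mild multiplicative texture so frames carry registration-usable detail
    texture = _smooth_noise(rng, shape, spacing, fwhm_mm=2.5 * float(spacing.mean()))
    activity *= 1.0 + 0.08 * texture
    np.clip(activity, 0.0, None, out=activity)

    if contrast == "met_like":
        fdg_mean = activity.mean()
        flattened = np.sqrt(activity)
        activity = flattened * (0.5 * fdg_mean / flattened.mean())

    names = dict(_LABELS)
    gray = (1, 2, 3, 4, 5, 6, 7, 8)
    roi_defs: dict[str, tuple[int, ...]] = {names[k]: (k,) for k in names}
    roi_defs["GM"] = gray
    roi_defs["WB"] = tuple(names)

    return LabeledPhantom(
        activity=VolumeGrid(activity, spacing, origin),
        labels=VolumeGrid(labels.astype(float), spacing, origin),
        label_names=names,
        roi_definitions=roi_defs,
        brain_center=center,
        contrast=contrast,
    )


@dataclass
class TrajectorySpec:
    """Declarative description of a rigid head-motion trajectory.

    ``pattern`` is one of ``static`` (no motion), ``drift`` (parameters
    linear in frame mid-time, reaching the full amplitude at scan end),
    ``step`` (identity before ``event_time_s``, constant amplitude after),
    ``jitter`` (zero-mean seeded per-frame perturbations only), or
    ``composite`` (drift + step).  Gaussian jitter of the given standard
    deviations is added on top of any pattern.
    """

    pattern: str = "static"
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    event_time_s: float | None = None
    noise_translation_sd_mm: float = 0.0
    noise_rotation_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("static", "drift", "step", "jitter", "composite"):
            raise InvalidInputError(f"unknown trajectory pattern {self.pattern!r}")
        if self.noise_translation_sd_mm < 0 or self.noise_rotation_sd_deg < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")


def make_trajectory(
    spec: TrajectorySpec,
    timing: FrameTiming,
    reference_index: int = 0,
    center=(0.0, 0.0, 0.0),
) -> MotionTrajectory:
    """Realise a :class:`TrajectorySpec` as per-frame rigid transforms.

    The transform at ``reference_index`` is exactly the identity; all
    other frames are referred to it.  ``center`` is the rotation centre
    (normally the phantom's brain centre).
    """
    n = timing.n_frames
    if not 0 <= reference_index < n:
        raise InvalidInputError(f"reference_index {reference_index} out of range")
    amp = np.concatenate([
        np.asarray(spec.translation_mm, dtype=float),
        np.asarray(spec.rotation_deg, dtype=float),
    ])
    mid = timing.mid_s
    params = np.zeros((n, 6))

    if spec.pattern in ("drift", "composite"):
        denom = mid[-1] - mid[reference_index]
        frac = (mid - mid[reference_index]) / denom if denom != 0 else np.zeros(n)
        params += amp[None, :] * frac[:, None]
    if spec.pattern in ("step", "composite"):
        event = spec.event_time_s
        if event is None:
            event = timing.scan_start_s + 0.5 * (timing.scan_end_s - timing.scan_start_s)
        if not timing.scan_start_s <= event <= timing.scan_end_s:
            raise InvalidInputError(
                f"event_time_s={event} outside scan [{timing.scan_start_s}, {timing.scan_end_s}]"
            )
        params += amp[None, :] * (mid >= event)[:, None]

    sd = np.concatenate([
        np.full(3, spec.noise_translation_sd_mm),
        np.full(3, spec.noise_rotation_sd_deg),
    ])
    if np.any(sd > 0):
        rng = np.random.default_rng(spec.seed)
        params += rng.normal(0.0, 1.0, size=(n, 6)) * sd[None, :]

    center = np.asarray(center, dtype=float)
    transforms = [RigidTransform.from_params(p, center) for p in params]
    ref = transforms[reference_index]
    if not ref.is_identity():
        inv_ref = invert(ref)
        transforms = [compose(t, inv_ref) for t in transforms]
    transforms[reference_index] = RigidTransform.identity(center)
    return MotionTrajectory(transforms, timing, reference_index)


def _expectation_frames(
    ph: LabeledPhantom,
    traj: MotionTrajectory,
    timing: FrameTiming,
    counts_per_frame: float,
    psf_fwhm_mm: float,
) -> np.ndarray:
    act = ph.activity
    n = timing.n_frames
    out = np.empty((n,) + act.shape)
    sigma = None
    if psf_fwhm_mm and psf_fwhm_mm > 0:
        sigma = psf_fwhm_mm / 2.3548 / act.spacing
    for f in range(n):
        t = traj.transforms[f]
        # frame f shows the anatomy moved: sample activity at T_f^{-1}(x)
        vals = act.values if t.is_identity() else resample(act, invert(t)).values
        if sigma is not None:
            vals = ndimage.gaussian_filter(vals, sigma, mode="constant")
        total = vals.sum()
        if total <= 0:
            raise InvalidInputError(f"frame {f} expectation has no signal")
        out[f] = vals * (counts_per_frame / total)
    return out


def simulate_frames(
    ph: LabeledPhantom,
    traj: MotionTrajectory,
    timing: FrameTiming | None = None,
    counts_per_frame: float = DEFAULT_COUNTS_PER_FRAME,
    psf_fwhm_mm: float = 5.0,
    seed: int = 0,
    noise: bool = True,
) -> DynamicSeries:
    """Simulate a dynamic frame series under a motion trajectory.

    Each frame's expectation is the motion-displaced activity, blurred by
    an isotropic Gaussian PSF of ``psf_fwhm_mm`` and scaled so the
    expected total equals ``counts_per_frame`` (constant counts per frame,
    as in count-matched short-frame reconstructions).  With ``noise=True``
    a per-voxel Poisson draw is returned; otherwise the expectation itself
    (zero-noise mode).
    """
    timing = traj.timing if timing is None else timing
    if traj.n_frames != timing.n_frames:
        raise InvalidInputError("trajectory and timing lengths must match")
    if counts_per_frame <= 0:
        raise InvalidInputError("counts_per_frame must be positive")
    expect = _expectation_frames(ph, traj, timing, counts_per_frame, psf_fwhm_mm)
    if noise:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(expect).astype(float)
    else:
        frames = expect
    act = ph.activity
    return DynamicSeries(frames, act.spacing.copy(), act.origin.copy(), timing)


def simulate_static_pair(
    ph: LabeledPhantom,
    traj: MotionTrajectory,
    timing: FrameTiming | None = None,
    counts_per_frame: float = DEFAULT_COUNTS_PER_FRAME,
    psf_fwhm_mm: float = 5.0,
    seed: int = 0,
    noise: bool = True,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Simulate the uncorrected/corrected static image pair.

    Returns ``(noMC, ddMC_oracle)``: the duration-weighted integral of the
    uncorrected frames, and of the frames corrected with the *true*
    transforms (ground-truth correction, independent of any estimator).
    """
    timing = traj.timing if timing is None else timing
    series = simulate_frames(ph, traj, timing, counts_per_frame, psf_fwhm_mm, seed, noise)
    nomc = integrate(series, timing)
    ddmc = integrate(correct_series(series, traj), timing)
    return nomc, ddmc
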