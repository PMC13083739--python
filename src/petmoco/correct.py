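"""Inter-frame motion correction and static-image integration.

Correction here is image-space: each frame is resampled through its rigid
transform back into reference space (pull-back), the image-domain analogue
of incorporating motion estimates into a list-mode reconstruction.  Motion
*within* a frame is irreducible at this level.
"""

from __future__ import annotations

import numpy as np

from .frames import DynamicSeries, FrameTiming, MotionTrajectory
from .geometry import InvalidInputError, VolumeGrid, resample


def correct_series(series: DynamicSeries, traj: MotionTrajectory) -> DynamicSeries:
    """Resample every frame through its transform into reference space.

    The reference frame (identity transform) is passed through unchanged.
    Uses trilinear interpolation; out-of-field voxels become 0.
    """
    if series.n_frames != traj.n_frames:
        raise InvalidInputError(
            f"series has {series.n_frames} frames but trajectory has {traj.n_frames}"
        )
    out = np.empty_like(series.frames)
    for f in range(series.n_frames):
        t = traj.transforms[f]
        if t.is_identity():
            out[f] = series.frames[f]
        else:
            out[f] = resample(series.frame(f), t, interpolation="trilinear").values
    return DynamicSeries(out, series.spacing.copy(), series.origin.copy(), series.timing)


def integrate(series: DynamicSeries, timing: FrameTiming | None = None) -> VolumeGrid:
    """Duration-weighted voxelwise mean of the frames (a static image)."""
    timing = series.timing if timing is None else timing
    if timing.n_frames != series.n_frames:
        raise InvalidInputError("timing length does not match series")
    total = timing.total_duration_s
    if total <= 0:
        raise InvalidInputError("total frame duration must be positive")
    w = timing.duration_s / total
    values = np.tensordot(w, series.frames, axes=1)
    return VolumeGrid(values, series.spacing.copy(), series.origin.copy())
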