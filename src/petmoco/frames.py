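"""Shared time-series carriers: frame timing, dynamic series, trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import InvalidInputError, RigidTransform, VolumeGrid


@dataclass
class FrameTiming:
    """Per-frame start times and durations in seconds.

    Starts are strictly increasing, frames do not overlap and durations
    are positive.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float).reshape(-1)
        self.duration_s = np.asarray(self.duration_s, dtype=float).reshape(-1)
        if self.start_s.size == 0 or self.start_s.size != self.duration_s.size:
            raise InvalidInputError("start_s and duration_s must be equal-length, nonempty")
        if np.any(self.duration_s <= 0):
            raise InvalidInputError("frame durations must be positive")
        if np.any(np.diff(self.start_s) <= 0):
            raise InvalidInputError("frame starts must be strictly increasing")
        ends = self.start_s + self.duration_s
        if np.any(self.start_s[1:] < ends[:-1] - 1e-9):
            raise InvalidInputError("frames must not overlap")

    @classmethod
    def uniform(cls, n_frames: int, frame_duration_s: float, t0: float = 0.0) -> "FrameTiming":
        starts = t0 + frame_duration_s * np.arange(n_frames)
        return cls(starts, np.full(n_frames, float(frame_duration_s)))

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @property
    def total_duration_s(self) -> float:
        return float(self.duration_s.sum())

    @property
    def scan_start_s(self) -> float:
        return float(self.start_s[0])

    @property
    def scan_end_s(self) -> float:
        return float(self.end_s[-1])


@dataclass
class DynamicSeries:
    """A stack of frames sharing one grid, with timing.

    ``frames`` has shape (n_frames, nx, ny, nz); spacing/origin follow the
    :class:`~petmoco.geometry.VolumeGrid` convention.
    """

    frames: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    timing: FrameTiming

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise InvalidInputError("frames must be 4-D (t, x, y, z)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.frames.shape[0] != self.timing.n_frames:
            raise InvalidInputError(
                f"{self.frames.shape[0]} frames but {self.timing.n_frames} timing entries"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> VolumeGrid:
        return VolumeGrid(self.frames[i], self.spacing.copy(), self.origin.copy())

    @property
    def grid(self) -> VolumeGrid:
        """An empty volume describing the common grid geometry."""
        return VolumeGrid(np.zeros(self.frames.shape[1:]), self.spacing.copy(), self.origin.copy())


@dataclass
class MotionTrajectory:
    """One rigid transform per frame, referred to a reference frame.

    ``transforms[f]`` maps reference-space world coordinates into
    frame-``f`` space; the reference frame's transform is the identity.
    ``metric`` optionally records the per-frame registration similarity;
    ``reliable`` flags frames whose estimate is trustworthy.
    """

    transforms: list[RigidTransform]
    timing: FrameTiming
    reference_index: int
    metric: np.ndarray | None = None
    reliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transforms = list(self.transforms)
        if len(self.transforms) != self.timing.n_frames:
            raise InvalidInputError("one transform per frame required")
        if not 0 <= self.reference_index < len(self.transforms):
            raise InvalidInputError(f"reference_index {self.reference_index} out of range")
        if not self.transforms[self.reference_index].is_identity(atol=1e-6):
            raise InvalidInputError("reference-frame transform must be the identity")
        if self.metric is not None:
            self.metric = np.asarray(self.metric, dtype=float).reshape(-1)
            if self.metric.size != len(self.transforms):
                raise InvalidInputError("metric length mismatch")
        if self.reliable is not None:
            self.reliable = np.asarray(self.reliable, dtype=bool).reshape(-1)
            if self.reliable.size != len(self.transforms):
                raise InvalidInputError("reliable length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.transforms)
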