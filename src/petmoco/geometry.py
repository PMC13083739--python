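"""Rigid-body transform algebra and volumetric resampling.

World convention
----------------
All coordinates are RAS millimetres on axis-aligned regular grids: array
axis 0 is x (left->right), axis 1 is y (posterior->anterior), axis 2 is z
(inferior->superior).  The world position of the centre of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``.  Oblique or sheared
grids are not supported.

A :class:`RigidTransform` is parameterised by three rotation angles in
degrees (extrinsic rotations about the world x, y, z axes, applied as
``Rz @ Ry @ Rx``), a translation in mm, and an explicit rotation centre in
world mm.  A point ``p`` maps to ``R @ (p - center) + center + translation``.
Transforms conventionally map reference-space coordinates into frame space,
so correcting a frame means resampling it *through* its transform
(pull-back into reference space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3 or not np.all(np.isfinite(v)):
        raise InvalidInputError(f"{name} must be a finite 3-vector, got {x!r}")
    return v


@dataclass
class VolumeGrid:
    """A 3-D scalar field on a regular axis-aligned grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (arbitrary signal units); must be finite.
    spacing : float or (3,) array
        Per-axis voxel size in mm; strictly positive.
    origin : (3,) array
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidInputError(
                f"values must be 3-D, got ndim={self.values.ndim}"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def world_center(self) -> np.ndarray:
        """World coordinate of the grid centre (mm)."""
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.spacing

    def aligned_with(self, other: "VolumeGrid") -> bool:
        """True iff spacing, origin and shape match exactly."""
        return (
            self.shape == other.shape
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.origin, other.origin)
        )

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.spacing.copy(), self.origin.copy())

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same grid geometry, new values."""
        return VolumeGrid(np.asarray(values, dtype=float), self.spacing.copy(), self.origin.copy())


@dataclass
class RigidTransform:
    """6-DOF rigid transform with explicit rotation centre.

    ``apply(p) = R @ (p - center) + center + translation`` where
    ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (extrinsic world-axis rotations,
    angles in degrees).
    """

    rotations_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotations_deg = _as_vec3(self.rotations_deg, "rotations_deg")
        self.translations_mm = _as_vec3(self.translations_mm, "translations_mm")
        self.center_mm = _as_vec3(self.center_mm, "center_mm")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center, dtype=float))

    @classmethod
    def from_params(cls, params, center) -> "RigidTransform":
        """Build from a 6-vector ``(tx, ty, tz, rx, ry, rz)`` (mm, deg)."""
        p = np.asarray(params, dtype=float)
        return cls(p[3:6], p[0:3], center)

    def params(self) -> np.ndarray:
        """The 6-vector ``(tx, ty, tz, rx, ry, rz)``."""
        return np.concatenate([self.translations_mm, self.rotations_deg])

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix ``Rz @ Ry @ Rx``."""
        return Rotation.from_euler("xyz", self.rotations_deg, degrees=True).as_matrix()

    def apply(self, points) -> np.ndarray:
        """Map world point(s) (mm); ``points`` is (..., 3)."""
        p = np.asarray(points, dtype=float)
        rel = p - self.center_mm
        moved = rel @ self.matrix.T + self.center_mm + self.translations_mm
        return moved

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.all(np.abs(self.rotations_deg) <= atol)
            and np.all(np.abs(self.translations_mm) <= atol)
        )


def apply_transform(t: RigidTransform, point) -> np.ndarray:
    """Apply ``t`` to a world point (mm)."""
    return t.apply(point)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``b`` first, then ``a``.

    Both transforms must share the same rotation centre.
    """
    if not np.allclose(a.center_mm, b.center_mm, atol=1e-9):
        raise InvalidInputError(
            f"compose requires a common rotation centre, got {a.center_mm} vs {b.center_mm}"
        )
    ra, rb = a.matrix, b.matrix
    r = ra @ rb
    angles = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
    t = ra @ b.translations_mm + a.translations_mm
    return RigidTransform(angles, t, a.center_mm.copy())


def invert(t: RigidTransform) -> RigidTransform:
    """The inverse transform (same rotation centre)."""
    r = t.matrix
    angles = Rotation.from_matrix(r.T).as_euler("xyz", degrees=True)
    return RigidTransform(angles, -(r.T @ t.translations_mm), t.center_mm.copy())


_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def resample(
    v: VolumeGrid, t: RigidTransform, interpolation: str = "trilinear"
) -> VolumeGrid:
    """Resample ``v`` through ``t`` onto ``v``'s own grid.

    Each output voxel at world position ``x`` takes the value of ``v``
    sampled (trilinear or nearest) at ``t.apply(x)``; samples outside the
    field of view are 0.  This is the pull-back used for motion correction:
    ``resample(frame_f, T_f)`` brings frame ``f`` into reference space when
    ``T_f`` maps reference coordinates into frame-``f`` coordinates.
    """
    if interpolation not in _INTERP_ORDER:
        raise InvalidInputError(f"unknown interpolation {interpolation!r}")
    if any(n == 0 for n in v.shape):
        raise InvalidInputError(f"degenerate grid shape {v.shape}")
    order = _INTERP_ORDER[interpolation]
    if t.is_identity():
        return v.copy()
    r = t.matrix
    s = v.spacing
    # index-space affine: input_index = M @ output_index + offset
    m = r * s[None, :] / s[:, None]
    offset = (r @ (v.origin - t.center_mm) + t.center_mm + t.translations_mm - v.origin) / s
    out = ndimage.affine_transform(
        v.values, m, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )
    return VolumeGrid(out, s.copy(), v.origin.copy())
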