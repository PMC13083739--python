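"""File formats: NIfTI-1 volumes, tab-separated trajectory/metric tables.

Grids are written with a diagonal RAS affine (spacing on the diagonal,
origin in the fourth column); on load, non-orthogonal or negatively
oriented affines are rejected rather than silently reoriented.

The trajectory dialect is a TSV with one row per frame and columns
``frame_index, t_start_s, t_dur_s, rx_deg, ry_deg, rz_deg, tx_mm, ty_mm,
tz_mm, cx_mm, cy_mm, cz_mm``; comment lines (``#``) document the rotation
convention and carry the reference-frame index.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameTiming, MotionTrajectory
from .geometry import InvalidInputError, RigidTransform, VolumeGrid

TRAJECTORY_COLUMNS = [
    "frame_index", "t_start_s", "t_dur_s",
    "rx_deg", "ry_deg", "rz_deg",
    "tx_mm", "ty_mm", "tz_mm",
    "cx_mm", "cy_mm", "cz_mm",
]


def write_volume(v: VolumeGrid, path) -> None:
    affine = np.diag(np.append(v.spacing, 1.0))
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(v.values, affine), str(path))


def _check_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    """Validate a diagonal RAS affine; returns (spacing, origin)."""
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    scale = max(1.0, float(np.abs(np.diag(rot)).max()))
    if np.abs(off_diag).max() > 1e-4 * scale:
        raise InvalidInputError(
            f"{path}: oblique orientation not supported (non-diagonal affine)"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise InvalidInputError(
            f"{path}: grid must be RAS-oriented with positive spacing, got diag {diag}"
        )
    return diag.copy(), affine[:3, 3].copy()


def read_volume(path) -> VolumeGrid:
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several parse error types
        raise InvalidInputError(f"cannot read NIfTI volume {path}: {e}") from e
    spacing, origin = _check_affine(np.asarray(img.affine, dtype=float), path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return VolumeGrid(data, spacing, origin)


def write_series(frames: np.ndarray, spacing, origin, path) -> None:
    """Write a 4-D frame stack as NIfTI with time on the last axis."""
    affine = np.diag(np.append(np.asarray(spacing, dtype=float), 1.0))
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.moveaxis(frames, 0, -1), affine), str(path))


def read_series(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a 4-D NIfTI; returns (frames (t,x,y,z), spacing, origin)."""
    try:
        img = nib.load(str(path))
    except Exception as e:
        raise InvalidInputError(f"cannot read NIfTI series {path}: {e}") from e
    spacing, origin = _check_affine(np.asarray(img.affine, dtype=float), path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise InvalidInputError(f"{path}: expected a 3-D or 4-D volume")
    return np.moveaxis(data, -1, 0), spacing, origin


def write_trajectory(traj: MotionTrajectory, path) -> None:
    rows = []
    for f, t in enumerate(traj.transforms):
        rows.append([
            f, traj.timing.start_s[f], traj.timing.duration_s[f],
            *t.rotations_deg, *t.translations_mm, *t.center_mm,
        ])
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# rigid transforms, reference space -> frame space\n")
        fh.write("# rotation: extrinsic Rz*Ry*Rx about world axes, degrees; "
                 "point map R*(p-center)+center+translation\n")
        fh.write(f"# reference_index = {traj.reference_index}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trajectory(path) -> MotionTrajectory:
    reference_index = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "reference_index" in line:
                reference_index = int(line.split("=")[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in TRAJECTORY_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"trajectory file {path} is missing column {col!r}")
    df = df.sort_values("frame_index")
    timing = FrameTiming(df["t_start_s"].to_numpy(), df["t_dur_s"].to_numpy())
    transforms = [
        RigidTransform(
            row[["rx_deg", "ry_deg", "rz_deg"]].to_numpy(dtype=float),
            row[["tx_mm", "ty_mm", "tz_mm"]].to_numpy(dtype=float),
            row[["cx_mm", "cy_mm", "cz_mm"]].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    ]
    if reference_index is None:
        ids = [f for f, t in enumerate(transforms) if t.is_identity(atol=1e-9)]
        if not ids:
            raise InvalidInputError(
                f"{path}: no reference_index comment and no identity frame"
            )
        reference_index = ids[0]
    return MotionTrajectory(transforms, timing, reference_index)


def write_labels(labels: VolumeGrid, label_names: dict[int, str],
                 roi_definitions: dict[str, tuple[int, ...]],
                 volume_path, names_path) -> None:
    write_volume(labels, volume_path)
    payload = {
        "label_names": {str(k): v for k, v in label_names.items()},
        "roi_definitions": {k: list(v) for k, v in roi_definitions.items()},
    }
    Path(names_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_labels(volume_path, names_path):
    """Read a label volume plus its JSON sidecar.

    Returns ``(labels, label_names, roi_definitions)``; any voxel id not
    declared in the sidecar (other than background 0) is an error.
    """
    labels = read_volume(volume_path)
    payload = json.loads(Path(names_path).read_text())
    names = {int(k): v for k, v in payload["label_names"].items()}
    roi_defs = {k: tuple(v) for k, v in payload["roi_definitions"].items()}
    present = set(np.unique(labels.values.astype(int))) - {0}
    unknown = present - set(names)
    if unknown:
        raise InvalidInputError(
            f"label volume contains unknown ROI ids {sorted(unknown)}; "
            f"known: {sorted(names.items())}"
        )
    return labels, names, roi_defs


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
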