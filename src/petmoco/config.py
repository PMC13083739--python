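"""Run configuration: one JSON-serialisable object holding every parameter.

Defaults fix the pipeline's fixed constants: 70 mm probe offset, 1 mm /
2 mm category boundaries, 16 mm / 30% mask construction, 3 mm XC filter,
1 mm registration-QC tolerance, alpha = 0.05 with an 11-ROI Bonferroni
family, and 5e5 expected counts per frame.  All randomness flows from the
single root ``seed`` via fixed per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .geometry import InvalidInputError


@dataclass
class RunConfig:
    # phantom
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 3.0
    contrast: str = "fdg_like"
    # trajectory
    pattern: str = "static"
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    event_time_s: float | None = None
    noise_translation_sd_mm: float = 0.0
    noise_rotation_sd_deg: float = 0.0
    # timing / counts
    n_frames: int = 12
    frame_duration_s: float = 30.0
    reference_time_s: float = 0.0
    counts_per_frame: float = 5e5
    psf_fwhm_mm: float = 5.0
    noise: bool = True
    seed: int = 0
    # analysis parameters
    probe_offset_mm: float = 70.0
    low_boundary_mm: float = 1.0
    high_boundary_mm: float = 2.0
    cdth_bin_width_mm: float = 0.1
    mask_fwhm_mm: float = 16.0
    mask_threshold_frac: float = 0.30
    xc_fwhm_mm: float = 3.0
    presmooth_fwhm_mm: float = 6.0
    multires_levels: int = 2
    alpha: float = 0.05
    bonferroni_m: int = 11
    qc_tolerance_mm: float = 1.0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.translation_mm = tuple(float(x) for x in self.translation_mm)
        self.rotation_deg = tuple(float(x) for x in self.rotation_deg)
        if self.n_frames < 1:
            raise InvalidInputError("n_frames must be >= 1")
        if self.seed < 0 or self.seed >= 2**31:
            raise InvalidInputError("seed must be in [0, 2**31)")

    def substream(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        return (self.seed * 10007 + stage) % (2**31)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
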