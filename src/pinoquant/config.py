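"""Analysis configuration and physical calibration.

All coordinates in this package are 0-based ``(row, col)`` with pixel centers
at integer coordinates.  Physical calibration converts pixel/frame units to
nm/µm and seconds; defaults follow the acquisition settings the analyses were
designed around (80 nm/pixel, 3 s frame interval, 250 nm z-step).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError


@dataclass
class Calibration:
    """Physical calibration of an image stack.

    Parameters
    ----------
    pixel_size_nm : float
        Lateral sampling in nanometres per pixel.
    frame_interval_s : float, optional
        Time between frames (time-lapse stacks only).
    z_step_nm : float, optional
        Axial spacing between planes (z-stacks only).
    """

    pixel_size_nm: float = 80.0
    frame_interval_s: Optional[float] = 3.0
    z_step_nm: Optional[float] = 250.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be positive")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")
        if self.z_step_nm is not None and self.z_step_nm <= 0:
            raise ConfigurationError("z_step_nm must be positive")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the quantification pipeline.

    Defaults encode the analysis conventions used throughout:

    - structures below ``min_structure_area_px`` (5 px) are discarded;
    - a tubule is a membrane deformation longer than ``tubule_min_length_px``
      (6 px at 80 nm/pixel);
    - a tubule is marker-positive when its mean signal is at least
      ``positive_fold_threshold`` (1.5×) the cytoplasmic background,
      boundary inclusive;
    - cytoplasmic background is the mean over a
      ``background_square_px``-sided square (100 px);
    - cross-tubule profiles estimate background outside a
      ``profile_exclusion_window_px`` (15 px, odd) window centered on the
      tubule, sampled with ``profile_width_px``-wide (3 px) lines;
    - membrane time traces use a circular ROI of
      ``membrane_roi_diameter_px`` (10 px) and are peak-aligned at
      ``trace_align_time_s`` (15 s);
    - tracked structures with median radius below ``min_track_radius_nm``
      (400 nm) are excluded, as are tracks present in the first frame;
    - only macropinosomes larger than ``min_macropinosome_diameter_um``
      (1 µm) enter the circumference-CV analysis.
    """

    min_structure_area_px: int = 5
    tubule_min_length_px: int = 6
    positive_fold_threshold: float = 1.5
    background_square_px: int = 100
    profile_exclusion_window_px: int = 15
    profile_width_px: int = 3
    min_macropinosome_diameter_um: float = 1.0
    membrane_roi_diameter_px: int = 10
    trace_align_time_s: float = 15.0
    min_track_radius_nm: float = 400.0
    threshold_method: str = "otsu"
    absolute_threshold: Optional[float] = None
    random_seed: Optional[int] = None
    # tracking / maturation conventions (see docs/methods.md)
    max_displacement_nm: float = 1600.0
    max_gap: int = 2
    success_fold_threshold: float = 1.5
    success_min_frames: int = 2
    # CV convention: sample standard deviation (n-1). Set to 0 for population.
    cv_ddof: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive_fields = [
            "min_structure_area_px",
            "tubule_min_length_px",
            "background_square_px",
            "profile_exclusion_window_px",
            "profile_width_px",
            "min_macropinosome_diameter_um",
            "membrane_roi_diameter_px",
            "min_track_radius_nm",
            "max_displacement_nm",
            "success_min_frames",
        ]
        for name in positive_fields:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.positive_fold_threshold <= 0:
            raise ConfigurationError("positive_fold_threshold must be > 0")
        if self.profile_exclusion_window_px % 2 == 0:
            raise ConfigurationError("profile_exclusion_window_px must be odd")
        if self.threshold_method not in ("otsu", "absolute"):
            raise ConfigurationError(
                f"unknown threshold_method {self.threshold_method!r}"
            )
        if self.threshold_method == "absolute" and self.absolute_threshold is None:
            raise ConfigurationError(
                "threshold_method 'absolute' requires absolute_threshold"
            )
        if self.max_gap < 0:
            raise ConfigurationError("max_gap must be >= 0")
        if self.cv_ddof not in (0, 1):
            raise ConfigurationError("cv_ddof must be 0 or 1")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config fields: {sorted(unknown)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
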