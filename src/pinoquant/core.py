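"""Core in-memory containers: image stacks, ROI annotations, measurement tables.

Conventions
-----------
- Pixel coordinates are 0-based ``(row, col)``; pixel centers sit at integer
  coordinates.
- :class:`ImageStack` holds pixels as a 4-D float array indexed
  ``(frame_or_plane, channel, row, col)``.  A single container serves both
  time-lapses and z-stacks, distinguished by ``axis_kind``; pixel-level
  operations are identical for both.
- Intensities are converted to floating point on construction.  Saturation is
  not modeled: all downstream measurements are mean/sum statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Calibration
from .errors import ValidationError

AXIS_KINDS = ("time", "z")


@dataclass
class ImageStack:
    """Multi-channel 2-D image series with physical calibration.

    ``pixels`` is ``(n, c, rows, cols)`` where the leading axis is time or z
    depending on ``axis_kind``.
    """

    pixels: np.ndarray
    axis_kind: str = "time"
    pixel_size_nm: float = 80.0
    frame_interval_s: Optional[float] = None
    z_step_nm: Optional[float] = None
    channel_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[None, None]
        elif px.ndim == 3:
            # interpret as (channel, row, col) single frame
            px = px[None]
        if px.ndim != 4:
            raise ValidationError(
                f"pixels must be 4-D (frame, channel, row, col); got {px.ndim}-D"
            )
        if any(s < 1 for s in px.shape):
            raise ValidationError("all image dimensions must be >= 1")
        if not np.all(np.isfinite(px)):
            raise ValidationError("intensities must be finite")
        if np.any(px < 0):
            raise ValidationError("intensities must be non-negative")
        self.pixels = px
        if self.axis_kind not in AXIS_KINDS:
            raise ValidationError(f"axis_kind must be one of {AXIS_KINDS}")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if self.axis_kind == "time":
            if self.frame_interval_s is not None and self.frame_interval_s <= 0:
                raise ValidationError("frame_interval_s must be positive")
        else:
            if self.z_step_nm is not None and self.z_step_nm <= 0:
                raise ValidationError("z_step_nm must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(px.shape[1])]
        if len(self.channel_names) != px.shape[1]:
            raise ValidationError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{px.shape[1]} channels"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise ValidationError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        idx = int(channel)
        if not 0 <= idx < self.n_channels:
            raise ValidationError(
                f"channel index {idx} out of range [0, {self.n_channels})"
            )
        return idx

    def plane(self, frame: int, channel: int | str) -> np.ndarray:
        """Single-channel 2-D view of one frame/plane."""
        return self.pixels[frame, self.channel_index(channel)]

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            pixel_size_nm=self.pixel_size_nm,
            frame_interval_s=self.frame_interval_s,
            z_step_nm=self.z_step_nm,
        )

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame (time stacks)."""
        if self.axis_kind != "time" or self.frame_interval_s is None:
            raise ValidationError("times_s requires a calibrated time stack")
        return np.arange(self.n_frames) * self.frame_interval_s


ROI_KINDS = ("line", "point", "polygon", "square")


@dataclass
class RoiAnnotation:
    """A manually drawn region of interest.

    ``vertices`` are ``(row, col)`` pairs.  For ``kind='line'`` at least two
    vertices are required and ``width_px`` gives the sampling band width (the
    3-pixel-wide line convention).  ``kind='square'`` encodes an axis-aligned
    box by its two diagonal corners.
    """

    kind: str
    frame_index: int = 0
    vertices: Sequence[Tuple[float, float]] = field(default_factory=list)
    width_px: int = 3
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValidationError(f"unknown ROI kind {self.kind!r}")
        if self.frame_index < 0:
            raise ValidationError("frame_index must be >= 0")
        self.vertices = [(float(r), float(c)) for r, c in self.vertices]
        if self.kind == "line" and len(self.vertices) < 2:
            raise ValidationError("line ROI needs >= 2 vertices")
        if self.kind == "point" and len(self.vertices) != 1:
            raise ValidationError("point ROI needs exactly 1 vertex")
        if self.kind == "square":
            if len(self.vertices) != 2:
                raise ValidationError(
                    "square ROI encodes an axis-aligned box by 2 corners"
                )
        if self.kind == "polygon" and len(self.vertices) < 3:
            raise ValidationError("polygon ROI needs >= 3 vertices")
        if self.width_px < 1:
            raise ValidationError("width_px must be >= 1")
        for r, c in self.vertices:
            if r < 0 or c < 0:
                raise ValidationError(
                    f"vertex ({r}, {c}) outside image bounds (negative)"
                )

    def validate_bounds(self, shape: Tuple[int, int]) -> None:
        rows, cols = shape
        for r, c in self.vertices:
            if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
                raise ValidationError(
                    f"vertex ({r}, {c}) outside image bounds {shape}"
                )

    def square_bounds(self) -> Tuple[int, int, int, int]:
        """(row0, col0, row1, col1) inclusive-exclusive box of a square ROI."""
        if self.kind != "square":
            raise ValidationError("square_bounds requires a square ROI")
        (r0, c0), (r1, c1) = self.vertices
        rmin, rmax = sorted((r0, r1))
        cmin, cmax = sorted((c0, c1))
        return int(round(rmin)), int(round(cmin)), int(round(rmax)) + 1, int(round(cmax)) + 1


# Fixed measurement-table schema.  Missing values are written as empty fields
# (pandas NaN) — the documented missing sentinel.
MEASUREMENT_COLUMNS = [
    "scope",
    "experiment_id",
    "cell_id",
    "structure_id",
    "frame",
    "metric_name",
    "value",
]

SCOPES = ("structure", "tubule", "cell", "track", "experiment")


class MeasurementTable:
    """Long-format measurement rows with a fixed, documented column order.

    Columns: ``scope, experiment_id, cell_id, structure_id, frame,
    metric_name, value``.  ``value`` is a float; missing values are NaN and
    serialize to empty CSV fields.
    """

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"measurement table missing columns {missing}")
        df = df[MEASUREMENT_COLUMNS].copy()
        bad = set(df["scope"].dropna()) - set(SCOPES)
        if bad:
            raise ValidationError(f"unknown scopes {sorted(bad)}")
        df["value"] = df["value"].astype(float)
        with np.errstate(invalid="ignore"):
            if np.any(np.isinf(df["value"].to_numpy(dtype=float))):
                raise ValidationError("values must be finite or missing (NaN)")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "MeasurementTable":
        rows = []
        for rec in records:
            row = {c: rec.get(c, np.nan) for c in MEASUREMENT_COLUMNS}
            rows.append(row)
        df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:  # value equality, NaN == NaN
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        a, b = self.df, other.df
        for col in MEASUREMENT_COLUMNS:
            if col == "value":
                va, vb = a[col].to_numpy(float), b[col].to_numpy(float)
                if not np.array_equal(va, vb, equal_nan=True):
                    return False
            else:
                sa = a[col].astype("string")
                sb = b[col].astype("string")
                if not sa.fillna("").eq(sb.fillna("")).all():
                    return False
        return True
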