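"""Moving circular-ROI intensity traces on the limiting membrane over time.

For each tracked membrane point a circular ROI (diameter of ten pixels by
default) is averaged in every channel per frame.  Traces are normalized
against their own time-series mean and aligned by whole samples so the
reference-channel peak (the nascent-membrane marker) lands at a fixed
acquisition timepoint (15 s at 3 s intervals → sample index 5).  Shifts are
whole samples only — the alignment timepoint is an acquisition frame, so no
sub-frame interpolation is performed — and shifted-out samples are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .core import ImageStack
from .errors import ConfigurationError, NormalizationError, ValidationError
from .stats import nan_mean_ci
from .synth import disc_mask


@dataclass
class MembraneTrace:
    """Per-frame multi-channel ROI means at uniform frame spacing."""

    vesicle_id: str
    times_s: np.ndarray            # strictly increasing, uniform spacing
    values: np.ndarray             # (n_samples, n_channels), NaN = missing
    roi_diameter_px: int = 10
    normalized: bool = False
    align_shift_samples: int = 0
    channel_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("trace needs >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise ValidationError("times must be strictly increasing, uniform")
        if v.shape[0] != t.size:
            raise ValidationError("values length must match times")
        self.times_s, self.values = t, v

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def sample_membrane_roi(
    stack: ImageStack,
    marks: Sequence[Tuple[int, Tuple[float, float]]],
    config: Optional[AnalysisConfig] = None,
    vesicle_id: str = "",
) -> MembraneTrace:
    """Quantify all channels in a circular ROI following membrane marks.

    ``marks`` is a list of ``(frame, (row, col))`` covering consecutive
    frames.  Per frame and channel the value is the mean over pixels whose
    centers lie within ``membrane_roi_diameter_px / 2`` of the mark; an ROI
    partially outside the image yields a missing (NaN) sample.
    """
    config = config or AnalysisConfig()
    if stack.frame_interval_s is None:
        raise ConfigurationError("stack needs frame_interval_s for traces")
    marks = sorted(marks, key=lambda m: m[0])
    frames = [f for f, _ in marks]
    if len(frames) < 2:
        raise ValidationError("need marks on >= 2 frames")
    if frames != list(range(frames[0], frames[-1] + 1)):
        raise ValidationError("marks must cover consecutive frames")
    radius = config.membrane_roi_diameter_px / 2.0
    shape = stack.frame_shape
    values = np.full((len(marks), stack.n_channels), np.nan)
    for i, (f, (r, c)) in enumerate(marks):
        if not (0 <= f < stack.n_frames):
            raise ValidationError(f"mark frame {f} outside the stack")
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise ValidationError(f"mark ({r}, {c}) outside image bounds")
        if (r - radius < -0.5 or c - radius < -0.5
                or r + radius > shape[0] - 0.5 or c + radius > shape[1] - 0.5):
            continue  # ROI partially outside: missing sample
        m = disc_mask(shape, (r, c), radius)
        for ch in range(stack.n_channels):
            values[i, ch] = float(stack.pixels[f, ch][m].mean())
    times = np.asarray(frames, dtype=float) * stack.frame_interval_s
    return MembraneTrace(
        vesicle_id=vesicle_id,
        times_s=times,
        values=values,
        roi_diameter_px=config.membrane_roi_diameter_px,
        channel_names=list(stack.channel_names),
    )


def normalize_trace(trace: MembraneTrace) -> MembraneTrace:
    """Normalize each channel against the mean of its own time series.

    Idempotent: a normalized trace has per-channel mean 1 and is returned
    unchanged (up to float rounding) on re-normalization.
    """
    means = np.nanmean(trace.values, axis=0)
    if np.any(~np.isfinite(means)) or np.any(means <= 0):
        raise NormalizationError("trace has a channel with non-positive mean")
    return replace(trace, values=trace.values / means[None, :], normalized=True)


@dataclass
class AggregatedTrace:
    """Across-vesicle mean trace with t-based 95% CI and per-time n."""

    times_s: np.ndarray
    mean: np.ndarray            # (n_times, n_channels)
    ci_half_width: np.ndarray   # NaN where n < 2
    n: np.ndarray               # (n_times,)
    align_index: Optional[int] = None
    traces: List[MembraneTrace] = None


def align_traces(
    traces: Sequence[MembraneTrace],
    reference_channel: int | str = 0,
    config: Optional[AnalysisConfig] = None,
    align: bool = True,
    peak_window: Optional[Tuple[int, int]] = None,
) -> AggregatedTrace:
    """Peak-align traces at a fixed timepoint and aggregate.

    Each trace is shifted by whole samples so its reference-channel maximum
    (ties → earliest; restricted to ``peak_window`` sample indices when
    given, e.g. an annotated nascent window) lands at the sample whose time
    equals ``trace_align_time_s`` (15 s at 3 s spacing → index 5).
    ``align=False`` aggregates without shifting — the variant used when the
    reference marker is pharmacologically removed and has no peak.
    All available samples contribute at each timepoint; per-time n is
    reported and the CI is undefined (NaN) where n < 2.
    """
    config = config or AnalysisConfig()
    if not traces:
        raise ValidationError("need at least one trace")
    dt = traces[0].frame_interval_s
    n_ch = traces[0].n_channels
    for tr in traces:
        if not np.isclose(tr.frame_interval_s, dt):
            raise ValidationError("traces must share the frame interval")
        if tr.n_channels != n_ch:
            raise ValidationError("traces must share the channel count")
    out_len = max(tr.values.shape[0] for tr in traces)
    if align:
        ratio = config.trace_align_time_s / dt
        target = int(round(ratio))
        if not np.isclose(ratio, target):
            raise ConfigurationError(
                f"trace_align_time_s={config.trace_align_time_s} is not a "
                f"multiple of the frame interval {dt}"
            )
        out_len = max(out_len, target + 1)
    grid = np.full((len(traces), out_len, n_ch), np.nan)
    shifted: List[MembraneTrace] = []
    for k, tr in enumerate(traces):
        if align:
            ref = (tr.values[:, tr.channel_names.index(reference_channel)]
                   if isinstance(reference_channel, str)
                   else tr.values[:, int(reference_channel)])
            lo, hi = (0, ref.size) if peak_window is None else peak_window
            seg = ref[lo:hi]
            if np.all(np.isnan(seg)):
                raise ValidationError(f"trace {k}: reference channel all-missing")
            peak = lo + int(np.nanargmax(seg))
            shift = target - peak
        else:
            shift = 0
        L = tr.values.shape[0]
        src_lo, src_hi = max(0, -shift), min(L, out_len - shift)
        grid[k, src_lo + shift:src_hi + shift] = tr.values[src_lo:src_hi]
        shifted.append(replace(tr, align_shift_samples=shift))
    mean, half, n = nan_mean_ci(grid, axis=0)
    return AggregatedTrace(
        times_s=np.arange(out_len) * dt,
        mean=mean,
        ci_half_width=half,
        n=n.max(axis=1) if n.ndim > 1 else n,
        align_index=target if align else None,
        traces=shifted,
    )
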