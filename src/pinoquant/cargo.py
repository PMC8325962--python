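"""Whole-cell and per-organelle fluid-phase (dextran) quantification, plus
masked Pearson colocalization.

Whole-cell dextran is measured on a sum projection of a z-stack: the total
in-cell intensity minus the mean of a 100×100 px background square outside
cells times the in-cell pixel count.  The background-subtracted total may be
negative at low signal and is deliberately not clamped, which keeps
per-experiment averages unbiased.  Organelle-associated dextran is measured
on the most in-focus plane (normalized-variance autofocus): organelles of at
least five pixels are segmented from their marker channel inside the cell
mask and the dextran summed over their pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .config import AnalysisConfig
from .core import ImageStack, RoiAnnotation
from .errors import (
    ConfigurationError,
    UndefinedStatisticError,
    ValidationError,
)
from .vesicles import segment_structures


@dataclass
class CellMeasurement:
    cell_id: str
    experiment_id: str
    total_dextran: float
    organelle_dextran: float
    n_organelles: int


def sum_projection(zstack: ImageStack) -> np.ndarray:
    """Pixelwise sum of intensities across z, per channel.

    Returns ``(channels, rows, cols)``.  Only defined for z-stacks.
    """
    if zstack.axis_kind != "z":
        raise ConfigurationError("sum_projection requires a z-stack")
    return zstack.pixels.sum(axis=0)


def best_focus_plane(zstack: ImageStack, channel: int | str) -> int:
    """Index of the most in-focus plane by normalized intensity variance
    (variance / mean²); ties resolve to the lowest index."""
    if zstack.n_frames < 1:
        raise ValidationError("empty stack")
    ch = zstack.channel_index(channel)
    scores = np.empty(zstack.n_frames)
    for i in range(zstack.n_frames):
        plane = zstack.pixels[i, ch]
        mean = plane.mean()
        scores[i] = plane.var() / mean**2 if mean > 0 else 0.0
    return int(np.argmax(scores))


MaskLike = Union[np.ndarray, RoiAnnotation]


def _as_mask(mask: MaskLike, shape: Tuple[int, int]) -> np.ndarray:
    if isinstance(mask, RoiAnnotation):
        if mask.kind != "polygon":
            raise ValidationError("cell mask ROI must be a polygon")
        from skimage.draw import polygon2mask

        return polygon2mask(shape, np.asarray(mask.vertices))
    mask = np.asarray(mask)
    if mask.shape != shape:
        raise ValidationError(f"mask shape {mask.shape} != image {shape}")
    return mask.astype(bool)


def whole_cell_dextran(
    projection: np.ndarray,
    cell_mask: MaskLike,
    background_square: RoiAnnotation,
) -> float:
    """Background-subtracted summed dextran intensity inside one cell.

    ``projection`` is the dextran channel of a sum projection.  The
    background square must lie outside all cells; its mean times the in-mask
    pixel count is subtracted from the in-mask total.
    """
    projection = np.asarray(projection, dtype=float)
    mask = _as_mask(cell_mask, projection.shape)
    r0, c0, r1, c1 = background_square.square_bounds()
    if r0 < 0 or c0 < 0 or r1 > projection.shape[0] or c1 > projection.shape[1]:
        raise ValidationError("background square outside image")
    if mask[r0:r1, c0:c1].any():
        raise ValidationError("background square overlaps the cell mask")
    background = float(projection[r0:r1, c0:c1].mean())
    return float(projection[mask].sum() - background * mask.sum())


def organelle_dextran(
    plane: np.ndarray,
    organelle_channel: int,
    dextran_channel: int,
    cell_mask: MaskLike,
    config: Optional[AnalysisConfig] = None,
    cell_id: str = "cell",
    experiment_id: str = "",
    total_dextran: float = float("nan"),
) -> CellMeasurement:
    """Dextran intensity within marker-positive organelles of one cell.

    ``plane`` is ``(channels, rows, cols)`` — the most in-focus plane.
    Organelles of at least ``min_structure_area_px`` (5 px) are segmented
    from the organelle marker channel inside the cell mask; the measurement
    is the dextran sum over all organelle pixels.  Per-experiment
    normalization is applied downstream
    (:func:`pinoquant.vesicles.normalize_by_experiment`).
    """
    config = config or AnalysisConfig()
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 3:
        raise ValidationError("plane must be (channels, rows, cols)")
    mask = _as_mask(cell_mask, plane.shape[1:])
    labels = segment_structures(plane[organelle_channel], config,
                                restrict_mask=mask)
    organelle_px = labels.labels > 0
    return CellMeasurement(
        cell_id=cell_id,
        experiment_id=experiment_id,
        total_dextran=total_dextran,
        organelle_dextran=float(plane[dextran_channel][organelle_px].sum()),
        n_organelles=labels.n_structures,
    )


def pearson_coloc(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: Optional[MaskLike] = None,
) -> float:
    """Pearson correlation coefficient between two channels within a mask."""
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValidationError("channels must share shape")
    if mask is None:
        a, b = ch1.ravel(), ch2.ravel()
    else:
        m = _as_mask(mask, ch1.shape)
        a, b = ch1[m], ch2[m]
    if a.size < 2:
        raise ValidationError("need >= 2 in-mask pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError(
            "Pearson undefined: a channel is constant within the mask"
        )
    return float(np.corrcoef(a, b)[0, 1])
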