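"""Segmentation of marker-positive structures and per-structure intensity
measurement, with per-experiment normalization.

This implements the endogenous-marker-on-organelle analysis: structures of at
least five pixels are segmented from a marker channel, the mean pixel
intensity of each structure is measured in a second channel, and each dataset
is normalized by the mean of its entire experiment to control for staining
and acquisition variation.

No implicit background subtraction happens at this stage: adding a constant
``c`` to the measured channel raises every structure mean by exactly ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .config import AnalysisConfig
from .core import MeasurementTable
from .errors import NormalizationError, SegmentationError, ValidationError


@dataclass
class LabelMask:
    """Integer-labeled 8-connected components of one image plane.

    Labels run consecutively from 1 to ``n_structures``; 0 is background.
    """

    labels: np.ndarray
    n_structures: int

    def mask(self, structure_id: int) -> np.ndarray:
        return self.labels == structure_id


@dataclass
class StructureRecord:
    structure_id: int
    area_px: int
    centroid: Tuple[float, float]
    mean_intensity: np.ndarray  # per channel
    sum_intensity: np.ndarray   # per channel
    image_id: str = ""
    cell_id: Optional[str] = None


def _threshold(plane: np.ndarray, config: AnalysisConfig) -> float:
    if config.threshold_method == "absolute":
        return float(config.absolute_threshold)
    if np.ptp(plane) == 0:
        raise SegmentationError(
            "Otsu threshold undefined on a constant image; use an absolute "
            "threshold instead"
        )
    return float(threshold_otsu(plane))


def segment_structures(
    plane: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    restrict_mask: Optional[np.ndarray] = None,
) -> LabelMask:
    """Threshold and label marker-positive structures in a single channel.

    Foreground is ``plane >= threshold`` with the configured absolute
    threshold, or ``plane > threshold`` under Otsu.  Components are
    8-connected; components smaller than ``min_structure_area_px`` are
    removed and the survivors relabeled consecutively from 1.
    ``restrict_mask`` optionally limits segmentation to in-mask pixels.
    """
    config = config or AnalysisConfig()
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValidationError("segment_structures expects a 2-D plane")
    if not np.all(np.isfinite(plane)):
        raise ValidationError("plane must be finite")
    work = plane
    if restrict_mask is not None:
        restrict_mask = np.asarray(restrict_mask, dtype=bool)
        if restrict_mask.shape != plane.shape:
            raise ValidationError("restrict_mask shape mismatch")
        work = np.where(restrict_mask, plane, plane.min())
    thr = _threshold(work if restrict_mask is None else plane[restrict_mask],
                     config)
    if config.threshold_method == "absolute":
        fg = work >= thr
    else:
        fg = work > thr
    if restrict_mask is not None:
        fg &= restrict_mask
    labels = sk_label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= config.min_structure_area_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelMask(labels=remap[labels], n_structures=int(keep.size))


def measure_structures(
    mask: LabelMask,
    planes: np.ndarray,
    image_id: str = "",
    cell_id: Optional[str] = None,
) -> List[StructureRecord]:
    """Per-structure mean and sum intensity in every channel.

    ``planes`` is ``(channels, rows, cols)`` or a single 2-D plane.
    """
    planes = np.asarray(planes, dtype=float)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.shape[1:] != mask.labels.shape:
        raise ValidationError(
            f"plane shape {planes.shape[1:]} does not match mask "
            f"{mask.labels.shape}"
        )
    n = mask.n_structures
    if n == 0:
        return []
    lab = mask.labels.ravel()
    areas = np.bincount(lab, minlength=n + 1)[1:]
    rr, cc = np.indices(mask.labels.shape)
    sum_r = np.bincount(lab, weights=rr.ravel(), minlength=n + 1)[1:]
    sum_c = np.bincount(lab, weights=cc.ravel(), minlength=n + 1)[1:]
    sums = np.stack([
        np.bincount(lab, weights=p.ravel(), minlength=n + 1)[1:]
        for p in planes
    ])  # (channels, n)
    records = []
    for i in range(n):
        records.append(StructureRecord(
            structure_id=i + 1,
            area_px=int(areas[i]),
            centroid=(sum_r[i] / areas[i], sum_c[i] / areas[i]),
            mean_intensity=sums[:, i] / areas[i],
            sum_intensity=sums[:, i].copy(),
            image_id=image_id,
            cell_id=cell_id,
        ))
    return records


GroupedValues = Union[pd.DataFrame, Dict[str, Sequence[float]]]


def normalize_by_experiment(
    records: GroupedValues,
    value_column: str = "value",
    experiment_column: str = "experiment_id",
    metric_name: str = "normalized_intensity",
) -> MeasurementTable:
    """Divide each value by the mean of all values in its experiment.

    Accepts either ``{experiment_id: [values]}`` or a DataFrame with an
    experiment column and a value column.  After normalization the mean of
    each experiment's values is exactly 1, which removes per-experiment
    staining/acquisition gain.
    """
    if isinstance(records, dict):
        rows = [
            {experiment_column: exp, value_column: float(v)}
            for exp, vals in records.items() for v in vals
        ]
        df = pd.DataFrame(rows)
    else:
        df = records.copy()
    if df.empty:
        raise ValidationError("no values to normalize")
    for col in (experiment_column, value_column):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}")
    values = df[value_column].astype(float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("values must be finite")
    out_rows = []
    for exp, sub in df.groupby(experiment_column, sort=False):
        mean = float(sub[value_column].mean())
        if mean == 0:
            raise NormalizationError(
                f"experiment {exp!r} has zero mean; cannot normalize"
            )
        for _, row in sub.iterrows():
            out_rows.append({
                "scope": "structure",
                "experiment_id": exp,
                "cell_id": row.get("cell_id", np.nan),
                "structure_id": row.get("structure_id", np.nan),
                "frame": row.get("frame", np.nan),
                "metric_name": metric_name,
                "value": float(row[value_column]) / mean,
            })
    return MeasurementTable.from_records(out_rows)
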