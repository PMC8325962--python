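"""Readers and writers: multi-page TIFF stacks, ROI tables, measurement CSVs.

Image layout on disk
--------------------
A stack is written as a multi-page TIFF with pages in frame-major,
channel-minor order (page ``k`` holds frame ``k // n_channels``, channel
``k % n_channels``).  A sidecar JSON file at ``<image>.json`` records the
axis kind, calibration and channel names, so a written stack is
self-describing; when the sidecar is absent a :class:`~pinoquant.config.Calibration`
plus channel count must be supplied by the caller.

ROI tables
----------
CSV with columns ``kind, frame, label, width_px, vertices`` where vertices
are semicolon-separated ``row:col`` pairs; an equivalent JSON list of objects
is accepted.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile

from .config import Calibration
from .core import MEASUREMENT_COLUMNS, ImageStack, MeasurementTable, RoiAnnotation
from .errors import FormatError, InputError, OutputError, ValidationError


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_image_stack(stack: ImageStack, path: str | Path, dtype=None) -> None:
    """Write a stack as a multi-page TIFF plus a calibration sidecar JSON.

    ``dtype`` defaults to float32; pass an integer dtype (e.g. ``np.uint16``)
    to preserve integer data bit-exactly.
    """
    path = Path(path)
    dtype = np.dtype(dtype) if dtype is not None else np.float32
    n, c, rows, cols = stack.pixels.shape
    pages = stack.pixels.reshape(n * c, rows, cols).astype(dtype)
    try:
        tifffile.imwrite(path, pages, photometric="minisblack")
    except OSError as exc:
        raise OutputError(f"cannot write image to {path}: {exc}") from exc
    meta = {
        "axis_kind": stack.axis_kind,
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "z_step_nm": stack.z_step_nm,
        "channel_names": stack.channel_names,
        "n_frames": n,
        "n_channels": c,
        "page_order": "frame_major",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_image_stack(
    path: str | Path,
    calibration: Optional[Calibration] = None,
    n_channels: Optional[int] = None,
    axis_kind: str = "time",
    channel_names: Optional[List[str]] = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    A sidecar JSON written by :func:`write_image_stack` supplies calibration
    and channel layout; explicit arguments are used when no sidecar exists.
    Integer pixel data are preserved bit-exactly (as float64 values).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = [p.shape for p in tif.pages]
            first = shapes[0]
            for i, shp in enumerate(shapes):
                if shp != first:
                    raise FormatError(
                        f"page {i} shape {shp} differs from page 0 shape {first}"
                    )
                if len(shp) != 2:
                    raise FormatError(f"page {i} is not a 2-D plane: shape {shp}")
            pages = np.asarray([p.asarray() for p in tif.pages])
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - tifffile internals
        raise FormatError(f"cannot parse TIFF {path}: {exc}") from exc
    if not np.issubdtype(pages.dtype, np.integer) and not np.issubdtype(
        pages.dtype, np.floating
    ):
        raise FormatError(f"unsupported pixel dtype {pages.dtype} in {path}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        n_channels = int(meta["n_channels"])
        axis_kind = meta["axis_kind"]
        channel_names = meta["channel_names"]
        calibration = Calibration(
            pixel_size_nm=meta["pixel_size_nm"],
            frame_interval_s=meta.get("frame_interval_s"),
            z_step_nm=meta.get("z_step_nm"),
        )
    if n_channels is None:
        n_channels = 1
    if calibration is None:
        calibration = Calibration()
    n_pages = pages.shape[0]
    if n_pages % n_channels:
        raise FormatError(
            f"{n_pages} pages not divisible by {n_channels} channels"
        )
    pixels = pages.reshape(n_pages // n_channels, n_channels, *pages.shape[1:])
    return ImageStack(
        pixels=pixels,
        axis_kind=axis_kind,
        pixel_size_nm=calibration.pixel_size_nm,
        frame_interval_s=calibration.frame_interval_s if axis_kind == "time" else None,
        z_step_nm=calibration.z_step_nm if axis_kind == "z" else None,
        channel_names=channel_names,
    )


# -- ROI annotations -------------------------------------------------------

_ROI_FIELDS = ["kind", "frame", "label", "width_px", "vertices"]


def _roi_from_record(rec: dict, index: int, default_width: int) -> RoiAnnotation:
    try:
        if isinstance(rec.get("vertices"), str):
            verts = []
            for pair in rec["vertices"].split(";"):
                pair = pair.strip()
                if not pair:
                    continue
                r, c = pair.split(":")
                verts.append((float(r), float(c)))
        else:
            verts = [(float(r), float(c)) for r, c in rec.get("vertices", [])]
        width = rec.get("width_px")
        width = default_width if width in (None, "") else int(width)
        return RoiAnnotation(
            kind=str(rec["kind"]).strip(),
            frame_index=int(rec.get("frame") or 0),
            vertices=verts,
            width_px=width,
            label=str(rec.get("label") or ""),
        )
    except ValidationError as exc:
        raise ValidationError(f"ROI record {index}: {exc}") from exc
    except (KeyError, ValueError) as exc:
        raise FormatError(f"ROI record {index}: cannot parse ({exc})") from exc


def load_roi_annotations(
    path: str | Path,
    image_shape: Optional[tuple] = None,
    default_width_px: int = 3,
) -> List[RoiAnnotation]:
    """Load ROI annotations from CSV or JSON.

    Line widths default to ``default_width_px`` (the 3-pixel-wide line
    convention) when absent.  With ``image_shape`` given, vertices are
    validated against the image bounds; negative coordinates are always
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"ROI file not found: {path}")
    records: List[dict] = []
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise FormatError(f"{path}: JSON ROI file must be a list of objects")
        records = data
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "kind" not in reader.fieldnames:
                raise FormatError(f"{path}: missing CSV header with 'kind' column")
            records = list(reader)
    rois = []
    for i, rec in enumerate(records):
        roi = _roi_from_record(rec, i, default_width_px)
        if image_shape is not None:
            try:
                roi.validate_bounds(image_shape)
            except ValidationError as exc:
                raise ValidationError(f"ROI record {i}: {exc}") from exc
        rois.append(roi)
    return rois


def write_roi_annotations(rois: List[RoiAnnotation], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ROI_FIELDS)
        for roi in rois:
            verts = ";".join(f"{r:g}:{c:g}" for r, c in roi.vertices)
            writer.writerow([roi.kind, roi.frame_index, roi.label, roi.width_px, verts])


# -- measurement tables ----------------------------------------------------

def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a measurement table as CSV in the fixed column order.

    Missing values are written as empty fields; floats use repr precision so
    a read-back reproduces the table exactly.
    """
    path = Path(path)
    try:
        table.df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OutputError(f"cannot write measurements to {path}: {exc}") from exc


def read_measurements(path: str | Path) -> MeasurementTable:
    path = Path(path)
    if not path.exists():
        raise InputError(f"measurement file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return MeasurementTable(df)
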