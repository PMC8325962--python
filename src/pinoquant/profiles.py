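"""Membrane-contour and cross-tubule intensity profiling.

Implements the circumference analyses: tracing a closed contour around a
macropinosome limiting membrane, sampling a 3-pixel-wide intensity band along
or across it, the coefficient-of-variation tubulation statistic, tubule
detection from protrusion morphology, the 1.5×-background tubule positivity
classifier, and peak-aligned fold-change aggregation of cross-tubule line
profiles.

Conventions (see docs/methods.md):

- contours are traversed counter-clockwise starting at the boundary point
  nearest the image origin, resampled to ~1 px arc-length spacing;
- the CV uses the sample standard deviation (n−1 denominator) by default;
- the positivity boundary is inclusive: mean signal ≥ 1.5 × background;
- profiles are aligned by whole-sample shifts, padded with missing values —
  never wrapped, since a tubule cross-section is not periodic;
- peak ties resolve to the first occurrence along the drawn direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import disk, skeletonize

from .config import AnalysisConfig
from .core import RoiAnnotation
from .errors import (
    BackgroundError,
    ContourError,
    EligibilityError,
    UndefinedStatisticError,
    ValidationError,
)
from .stats import nan_mean_ci
from .vesicles import LabelMask


@dataclass
class MembraneContour:
    """Closed membrane path at ~1 px arc-length spacing (row, col)."""

    vesicle_id: str
    points: np.ndarray  # (n, 2), closed: first == last
    diameter_um: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ContourError("contour needs >= 8 (row, col) points")
        if not np.allclose(pts[0], pts[-1], atol=1e-6):
            raise ContourError("contour must be closed (first == last)")
        self.points = pts

    @property
    def n_samples(self) -> int:
        return self.points.shape[0] - 1  # closing point not a sample


@dataclass
class LineProfile:
    """Width-averaged intensity samples along a drawn path.

    ``values`` is ``(n_positions, n_channels)``; missing samples are NaN.
    ``background`` is filled per channel by fold-change normalization.
    """

    positions_px: np.ndarray
    values: np.ndarray
    width_px: int = 3
    alignment_offset: int = 0
    background: Optional[np.ndarray] = None
    channel_names: Optional[List[str]] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.shape[0] != self.positions_px.shape[0]:
            raise ValidationError("values length must equal positions length")
        if self.width_px < 1:
            raise ValidationError("width_px must be >= 1")
        self.values = vals

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, channel: int | str) -> np.ndarray:
        return self.values[:, self._index(channel)]

    def _index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            if not self.channel_names or channel not in self.channel_names:
                raise ValidationError(f"unknown channel {channel!r}")
            return self.channel_names.index(channel)
        return int(channel)


@dataclass
class TubuleSkeleton:
    """A detected membrane protrusion: skeleton pixels ordered from the root."""

    pixels: np.ndarray  # (n, 2) int
    length_px: float
    root: Tuple[float, float]


@dataclass
class TubuleCall:
    cell_id: str
    tubule_id: str
    length_px: float
    signal_intensity: float
    cytoplasmic_background: float
    positive: bool


# --------------------------------------------------------------------------
# contour extraction
# --------------------------------------------------------------------------

def _resample_closed(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed polyline to uniform ~``spacing`` arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / spacing)), 1)
    targets = np.linspace(0.0, total, n + 1)
    rows = np.interp(targets, arc, points[:, 0])
    cols = np.interp(targets, arc, points[:, 1])
    out = np.stack([rows, cols], axis=1)
    out[-1] = out[0]
    return out


def _orient_ccw_from_origin(points: np.ndarray) -> np.ndarray:
    """Fix traversal: counter-clockwise (image coords), start nearest origin."""
    ring = points[:-1]
    # signed area (shoelace) in (row, col); positive = counter-clockwise
    r, c = ring[:, 0], ring[:, 1]
    area = 0.5 * np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)
    if area < 0:
        ring = ring[::-1]
    start = int(np.argmin(np.hypot(ring[:, 0], ring[:, 1])))
    ring = np.roll(ring, -start, axis=0)
    return np.vstack([ring, ring[:1]])


def extract_contour(
    mask: LabelMask,
    label: int,
    pixel_size_nm: float,
    vesicle_id: str = "",
) -> MembraneContour:
    """Trace the sub-pixel outer boundary of one labeled structure.

    The iso-level 0.5 boundary between structure and background is traced on
    the hole-filled structure mask and resampled to ~1 px arc-length spacing.
    ``diameter_um`` is the equivalent-circle diameter
    ``2·sqrt(area/π)·pixel_size_nm/1000``.  Structures touching the image
    border have no complete circumference and raise :class:`ContourError`.
    """
    binary = mask.labels == label
    if not binary.any():
        raise ContourError(f"label {label} not present in mask")
    if (binary[0, :].any() or binary[-1, :].any()
            or binary[:, 0].any() or binary[:, -1].any()):
        raise ContourError(
            f"structure {label} touches the image border; "
            "circumference incomplete"
        )
    filled = ndimage.binary_fill_holes(binary)
    contours = find_contours(filled.astype(float), 0.5)
    if not contours:
        raise ContourError(f"no contour found for label {label}")
    outer = max(contours, key=lambda c: c.shape[0])
    resampled = _resample_closed(outer, spacing=1.0)
    if resampled.shape[0] - 1 < 8:
        raise ContourError(
            f"structure {label} below resolvable circumference (< 8 samples)"
        )
    area = float(filled.sum())
    diameter_um = 2.0 * np.sqrt(area / np.pi) * pixel_size_nm / 1000.0
    return MembraneContour(
        vesicle_id=vesicle_id or str(label),
        points=_orient_ccw_from_origin(resampled),
        diameter_um=diameter_um,
    )


def snap_contour_to_ridge(
    contour: MembraneContour,
    plane: np.ndarray,
    search_px: float = 3.0,
    step_px: float = 0.25,
    smooth: int = 3,
) -> MembraneContour:
    """Refine a contour onto the membrane intensity ridge.

    A thresholded structure boundary sits on the outer flank of the membrane
    cross-section; each contour point is therefore moved along its local
    normal to the position of maximum intensity within ``±search_px``
    (sub-pixel grid of ``step_px``), then lightly smoothed along the path.
    This reproduces drawing the line *on* the membrane, so that band profiles
    sample the ridge rather than the flank.
    """
    plane = np.asarray(plane, dtype=float)
    ring = contour.points[:-1]
    nxt = np.roll(ring, -1, axis=0)
    prv = np.roll(ring, 1, axis=0)
    tangent = nxt - prv
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent /= norm
    normals = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    offsets = np.arange(-search_px, search_px + step_px / 2, step_px)
    coords = ring[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    rows = np.clip(coords[..., 0], 0, plane.shape[0] - 1)
    cols = np.clip(coords[..., 1], 0, plane.shape[1] - 1)
    samples = ndimage.map_coordinates(
        plane, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(offsets.size, ring.shape[0])
    best = offsets[np.argmax(samples, axis=0)]
    snapped = ring + best[:, None] * normals
    if smooth > 1:  # circular moving average to suppress jaggies
        kernel = np.ones(smooth) / smooth
        for d in range(2):
            padded = np.concatenate([snapped[-(smooth // 2):, d],
                                     snapped[:, d],
                                     snapped[:smooth // 2, d]])
            snapped[:, d] = np.convolve(padded, kernel, mode="valid")
    return MembraneContour(
        vesicle_id=contour.vesicle_id,
        points=np.vstack([snapped, snapped[:1]]),
        diameter_um=contour.diameter_um,
    )


# --------------------------------------------------------------------------
# band sampling
# --------------------------------------------------------------------------

def _band_sample(
    planes: np.ndarray,
    path: np.ndarray,
    normals: np.ndarray,
    width_px: int,
) -> np.ndarray:
    """Mean over ``width_px`` bilinear samples along the local normal.

    Positions whose band leaves the image are NaN (flagged missing).
    """
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    # sample coordinates: (width, n, 2)
    coords = path[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    rows, cols = coords[..., 0], coords[..., 1]
    nr, nc = planes.shape[1:]
    inside = (rows >= 0) & (rows <= nr - 1) & (cols >= 0) & (cols <= nc - 1)
    ok = inside.all(axis=0)  # whole band must stay inside
    out = np.full((path.shape[0], planes.shape[0]), np.nan)
    if ok.any():
        flat_r = rows[:, ok].ravel()
        flat_c = cols[:, ok].ravel()
        for c in range(planes.shape[0]):
            samp = ndimage.map_coordinates(
                planes[c], [flat_r, flat_c], order=1, mode="nearest"
            ).reshape(width_px, -1)
            out[ok, c] = samp.mean(axis=0)
    return out


def _as_planes(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise ValidationError("expected a 2-D plane or (channels, rows, cols)")
    return image


def contour_profile(
    image: np.ndarray,
    contour: MembraneContour,
    width_px: int = 3,
    channel_names: Optional[List[str]] = None,
) -> LineProfile:
    """Width-averaged intensity along a closed membrane contour.

    At each contour sample the intensity is the mean of ``width_px``
    bilinear samples spaced 1 px along the local normal, centered on the
    path (the 3-pixel-thick line convention).
    """
    planes = _as_planes(image)
    ring = contour.points[:-1]
    nxt = np.roll(ring, -1, axis=0)
    prv = np.roll(ring, 1, axis=0)
    tangent = nxt - prv
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent = tangent / norm
    normals = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    values = _band_sample(planes, ring, normals, width_px)
    return LineProfile(
        positions_px=np.arange(ring.shape[0], dtype=float),
        values=values,
        width_px=width_px,
        channel_names=channel_names,
        label=contour.vesicle_id,
    )


def line_profile(
    image: np.ndarray,
    roi: RoiAnnotation | Tuple[Tuple[float, float], Tuple[float, float]],
    width_px: Optional[int] = None,
    channel_names: Optional[List[str]] = None,
) -> LineProfile:
    """Width-averaged intensity along a straight line ROI at 1 px spacing."""
    planes = _as_planes(image)
    if isinstance(roi, RoiAnnotation):
        if roi.kind != "line":
            raise ValidationError("line_profile requires a line ROI")
        p0, p1 = np.asarray(roi.vertices[0]), np.asarray(roi.vertices[-1])
        width = width_px or roi.width_px
        label = roi.label
    else:
        p0, p1 = np.asarray(roi[0], float), np.asarray(roi[1], float)
        width = width_px or 3
        label = ""
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(round(length)), 1)
    ts = np.linspace(0.0, 1.0, n + 1)
    path = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    direction = (p1 - p0) / (length if length else 1.0)
    normal = np.array([-direction[1], direction[0]])
    normals = np.tile(normal, (path.shape[0], 1))
    values = _band_sample(planes, path, normals, width)
    return LineProfile(
        positions_px=np.arange(path.shape[0], dtype=float),
        values=values,
        width_px=width,
        channel_names=channel_names,
        label=label,
    )


# --------------------------------------------------------------------------
# tubulation CV
# --------------------------------------------------------------------------

def tubulation_cv(
    profile: LineProfile,
    channel: int | str = 0,
    diameter_um: Optional[float] = None,
    config: Optional[AnalysisConfig] = None,
) -> float:
    """Coefficient of variation of intensity along the membrane circumference.

    CV = sample standard deviation (n−1 denominator by default; see
    ``cv_ddof``) divided by the mean of the selected channel's non-missing
    samples.  Higher CV indicates more tubule-nucleation spots on the
    limiting membrane.  When ``diameter_um`` is supplied, vesicles at or
    below ``min_macropinosome_diameter_um`` (1 µm) are rejected as
    ineligible.
    """
    config = config or AnalysisConfig()
    if diameter_um is not None and diameter_um <= config.min_macropinosome_diameter_um:
        raise EligibilityError(
            f"macropinosome diameter {diameter_um:.3f} µm not above the "
            f"{config.min_macropinosome_diameter_um} µm inclusion threshold"
        )
    vals = profile.channel(channel)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValidationError("CV requires >= 2 non-missing samples")
    mean = float(np.mean(vals))
    if mean == 0:
        raise UndefinedStatisticError("CV undefined: profile mean is zero")
    return float(np.std(vals, ddof=config.cv_ddof) / mean)


# --------------------------------------------------------------------------
# tubule detection
# --------------------------------------------------------------------------

def _skeleton_main_path(pixels: np.ndarray, start_idx: int):
    """Geodesic path from a start pixel to the farthest skeleton pixel.

    Dijkstra over the 8-connected skeleton graph with diagonal steps
    weighted sqrt(2); robust to short side branches.  Returns the ordered
    main-path pixels and their geodesic length (+1 for the root pixel).
    """
    import heapq

    index = {tuple(p): i for i, p in enumerate(pixels)}
    n = len(pixels)
    dist = np.full(n, np.inf)
    prev = np.full(n, -1, dtype=int)
    dist[start_idx] = 0.0
    heap = [(0.0, start_idx)]
    while heap:
        d, i = heapq.heappop(heap)
        if d > dist[i]:
            continue
        r, c = pixels[i]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is None:
                    continue
                nd = d + (np.sqrt(2.0) if dr and dc else 1.0)
                if nd < dist[j]:
                    dist[j] = nd
                    prev[j] = i
                    heapq.heappush(heap, (nd, j))
    reached = np.flatnonzero(np.isfinite(dist))
    end = reached[np.argmax(dist[reached])]
    path = [end]
    while prev[path[-1]] != -1:
        path.append(prev[path[-1]])
    path.reverse()
    return pixels[path], float(dist[end]) + 1.0


def detect_tubules(
    vesicle_mask: np.ndarray,
    config: Optional[AnalysisConfig] = None,
) -> List[TubuleSkeleton]:
    """Detect membrane protrusions (tubules) on a single vesicle mask.

    The hole-filled mask is morphologically opened with a disc scaled to the
    vesicle-body radius; what the opening removes is the protrusions.  Each
    protrusion is skeletonized and kept when its skeleton length exceeds
    ``tubule_min_length_px`` (deformations of more than six pixels at
    80 nm/pixel).  Skeleton pixels are ordered from the root — the skeleton
    pixel nearest the vesicle body.
    """
    from .synth import disc_mask

    config = config or AnalysisConfig()
    binary = np.asarray(vesicle_mask).astype(bool)
    if not binary.any():
        return []
    filled = ndimage.binary_fill_holes(binary)
    # vesicle body modeled as a disc: center at the distance-transform peak,
    # radius the median center-to-boundary distance.  Root and tip both sit
    # at the same threshold iso-level, so their offsets cancel and the
    # skeleton length tracks the true protrusion length.
    edt = ndimage.distance_transform_edt(filled)
    center = np.unravel_index(int(np.argmax(edt)), edt.shape)
    boundary = filled & ~ndimage.binary_erosion(filled)
    bpix = np.argwhere(boundary)
    r_body = float(np.median(np.hypot(bpix[:, 0] - center[0],
                                      bpix[:, 1] - center[1])))
    body = disc_mask(filled.shape, center, r_body) & filled
    protrusions = filled & ~body
    if not protrusions.any():
        return []
    labels, n = ndimage.label(protrusions, structure=np.ones((3, 3), dtype=int))
    body_dist = ndimage.distance_transform_edt(~body)
    out: List[TubuleSkeleton] = []
    for lab in range(1, n + 1):
        component = labels == lab
        # length = radial reach of the protrusion beyond the body boundary;
        # root and tip sit at the same threshold iso-level so their offsets
        # cancel, and the measure is immune to skeleton end-shortening
        length = float(body_dist[component].max())
        if length <= max(2.0, float(config.tubule_min_length_px)):
            continue  # sliver hugging the body boundary, or too short
        skel = skeletonize(component)
        pixels = np.argwhere(skel if skel.any() else component)
        dists = body_dist[pixels[:, 0], pixels[:, 1]]
        ordered, _ = _skeleton_main_path(pixels, int(np.argmin(dists)))
        out.append(TubuleSkeleton(
            pixels=ordered,
            length_px=length,
            root=(float(ordered[0, 0]), float(ordered[0, 1])),
        ))
    return out


# --------------------------------------------------------------------------
# cytoplasmic background
# --------------------------------------------------------------------------

def cytoplasmic_background(
    plane: np.ndarray,
    square: Optional[RoiAnnotation] = None,
    config: Optional[AnalysisConfig] = None,
    cell_mask: Optional[np.ndarray] = None,
    exclude_mask: Optional[np.ndarray] = None,
    strict: bool = True,
) -> float:
    """Mean fluorescence over a background square (100×100 px by default).

    With an explicit ``square`` ROI the mean over that square is returned;
    in strict mode the square must lie inside ``cell_mask`` (when given) and
    off ``exclude_mask`` (segmented structures).  Without a square, auto
    placement raster-scans for the first valid position (deterministic) and
    raises :class:`BackgroundError` when none exists.
    """
    config = config or AnalysisConfig()
    plane = np.asarray(plane, dtype=float)
    side = config.background_square_px

    def _check(r0: int, c0: int) -> bool:
        if r0 < 0 or c0 < 0 or r0 + side > plane.shape[0] or c0 + side > plane.shape[1]:
            return False
        if cell_mask is not None and not cell_mask[r0:r0 + side, c0:c0 + side].all():
            return False
        if exclude_mask is not None and exclude_mask[r0:r0 + side, c0:c0 + side].any():
            return False
        return True

    if square is not None:
        r0, c0, r1, c1 = square.square_bounds()
        if strict and not _check(r0, c0):
            raise BackgroundError(
                "background square overlaps excluded structures or leaves "
                "the cell mask"
            )
        block = plane[r0:r1, c0:c1]
        if block.size == 0:
            raise BackgroundError("background square outside image")
        return float(block.mean())

    step = max(side // 4, 1)
    for r0 in range(0, plane.shape[0] - side + 1, step):
        for c0 in range(0, plane.shape[1] - side + 1, step):
            if _check(r0, c0):
                return float(plane[r0:r0 + side, c0:c0 + side].mean())
    raise BackgroundError(
        f"no valid {side}x{side} background placement found"
    )


# --------------------------------------------------------------------------
# tubule positivity classifier
# --------------------------------------------------------------------------

def classify_tubules(
    tubules: Sequence[TubuleSkeleton],
    signal_plane: np.ndarray,
    background: float,
    config: Optional[AnalysisConfig] = None,
    cell_id: str = "cell",
) -> List[TubuleCall]:
    """Classify each tubule as marker-positive against cytoplasmic background.

    The tubule signal is the mean of the signal channel over the skeleton
    dilated to the profile band width (3 px); a tubule is positive when
    signal ≥ ``positive_fold_threshold`` × background — boundary inclusive
    (a signal 50% above background counts as positive).
    """
    config = config or AnalysisConfig()
    if background <= 0:
        raise ValidationError("background must be positive")
    signal_plane = np.asarray(signal_plane, dtype=float)
    radius = (config.profile_width_px - 1) // 2
    calls = []
    for i, tub in enumerate(tubules):
        band = np.zeros(signal_plane.shape, dtype=bool)
        band[tub.pixels[:, 0], tub.pixels[:, 1]] = True
        if radius > 0:
            band = ndimage.binary_dilation(band, structure=disk(radius))
        signal = float(signal_plane[band].mean())
        calls.append(TubuleCall(
            cell_id=cell_id,
            tubule_id=f"{cell_id}/t{i}",
            length_px=tub.length_px,
            signal_intensity=signal,
            cytoplasmic_background=float(background),
            positive=bool(signal >= config.positive_fold_threshold * background),
        ))
    return calls


def positive_fraction_by_cell(calls: Sequence[TubuleCall]) -> Dict[str, float]:
    """Per-cell fraction of positive tubules; cells with zero tubules are NaN.

    Each cell is a single biological data point (proportion of tubules
    marker-positive).
    """
    cells: Dict[str, List[bool]] = {}
    for call in calls:
        cells.setdefault(call.cell_id, []).append(call.positive)
    return {
        cell: (float(np.mean(flags)) if flags else float("nan"))
        for cell, flags in cells.items()
    }


# --------------------------------------------------------------------------
# profile alignment and fold-change normalization
# --------------------------------------------------------------------------

@dataclass
class AggregatedProfile:
    """Peak-aligned, background-normalized mean profile with 95% CI."""

    positions: np.ndarray           # sample index relative to profile start
    center_index: int               # index where reference peaks sit
    mean: np.ndarray                # (n_positions, n_channels)
    ci_half_width: np.ndarray       # (n_positions, n_channels)
    n: np.ndarray                   # (n_positions,) profiles contributing
    aligned_profiles: List[LineProfile] = field(default_factory=list)


def align_and_normalize_profiles(
    profiles: Sequence[LineProfile],
    reference_channel: int | str = 0,
    config: Optional[AnalysisConfig] = None,
) -> AggregatedProfile:
    """Align profiles on the reference-channel peak and express them as
    fold-change over local cytoplasmic background.

    Each profile is shifted by whole samples so its reference-channel maximum
    (ties → first occurrence) lands at the common center index; shifted-out
    positions become missing.  The per-profile background per channel is the
    mean of samples outside a ``profile_exclusion_window_px``-wide window
    centered on the peak, and every channel is divided by that profile's own
    background, so values read as multiples of cytoplasmic background.  The
    aggregate is the per-position mean with a t-based 95% CI over profiles.
    """
    config = config or AnalysisConfig()
    if not profiles:
        raise ValidationError("need at least one profile")
    window = config.profile_exclusion_window_px
    half_w = window // 2
    out_len = max(p.values.shape[0] for p in profiles)
    if out_len < window + 2:
        raise ValidationError(
            f"profiles of length {out_len} too short for the "
            f"{window}-sample exclusion window"
        )
    center = out_len // 2
    n_ch = profiles[0].values.shape[1]
    aligned_vals = np.full((len(profiles), out_len, n_ch), np.nan)
    aligned_profiles: List[LineProfile] = []
    for k, prof in enumerate(profiles):
        if prof.values.shape[1] != n_ch:
            raise ValidationError("profiles must share the channel count")
        ref = prof.channel(reference_channel)
        if np.all(np.isnan(ref)):
            raise ValidationError(f"profile {k}: reference channel all-missing")
        peak = int(np.nanargmax(ref))
        shift = center - peak
        L = prof.values.shape[0]
        src_lo, src_hi = max(0, -shift), min(L, out_len - shift)
        dst_lo, dst_hi = src_lo + shift, src_hi + shift
        vals = np.full((out_len, n_ch), np.nan)
        vals[dst_lo:dst_hi] = prof.values[src_lo:src_hi]
        # fold-change normalization against the off-window mean
        off = np.ones(out_len, dtype=bool)
        off[max(0, center - half_w):center + half_w + 1] = False
        background = np.empty(n_ch)
        for c in range(n_ch):
            chan = vals[off, c]
            chan = chan[~np.isnan(chan)]
            if chan.size == 0:
                raise ValidationError(
                    f"profile {k}: no off-window samples for background"
                )
            bg = float(chan.mean())
            if bg == 0:
                raise ValidationError(f"profile {k}: zero background")
            background[c] = bg
        vals = vals / background[None, :]
        aligned_vals[k] = vals
        aligned_profiles.append(LineProfile(
            positions_px=np.arange(out_len, dtype=float),
            values=vals,
            width_px=prof.width_px,
            alignment_offset=shift,
            background=background,
            channel_names=prof.channel_names,
            label=prof.label,
        ))
    mean, half, n = nan_mean_ci(aligned_vals, axis=0)
    return AggregatedProfile(
        positions=np.arange(out_len, dtype=float),
        center_index=center,
        mean=mean,
        ci_half_width=half,
        n=n.max(axis=1) if n.ndim > 1 else n,
        aligned_profiles=aligned_profiles,
    )
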