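"""Synthetic fluorescence-microscopy scenes with exact ground truth.

The generator emulates the statistical structure the quantification modules
assume: cells with diffuse cytoplasmic background, ring-shaped macropinosome
limiting membranes (0.4–3 µm diameter at 80 nm/pixel), tubule protrusions
nucleating at bright membrane spots, punctate organelles, lumenal dextran
fill, a plasma-membrane outline channel, and — in time-lapses — Poisson
vesicle births, biphasic recruitment of a nascent-membrane marker, and
stochastic maturation (PtdIns3P-marker acquisition) versus re-fusion with the
plasma membrane.  Noise is Poisson shot noise plus Gaussian read noise,
applied last; every rendered structure is recorded in a
:class:`GroundTruth` that serves as the oracle for all tests.

Rendering conventions
---------------------
- Membranes (vesicle rings, tubules, the plasma-membrane band) have a
  Gaussian cross-section whose FWHM is ``membrane_thickness_px``.
- Lumen fills (vesicle interior and organelle dextran) and organelle marker
  puncta are hard pixel masks with constant level, so ground-truth sums are
  exact (level × pixel count).  Lumen dextran *replaces* the cytoplasm level
  inside the lumen.
- Cells are non-overlapping discs on a jittered grid.
- One RNG stream per render, seeded explicitly; layout and noise use
  sub-streams spawned from the seed so noise realizations do not perturb
  geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from math import ceil, cos, pi, sin, sqrt
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import ImageStack
from .errors import GenerationError, ValidationError

IntOrRange = Union[int, Tuple[int, int]]

SCENE_CHANNELS = ["membrane", "secondary", "organelle", "dextran", "pm"]
TIMELAPSE_CHANNELS = ["pm", "marker", "nascent"]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Poisson shot noise (``poisson_scale`` photons per intensity unit;
    0 disables) plus additive Gaussian read noise of ``read_sigma``."""

    poisson_scale: float = 1.0
    read_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.read_sigma < 0:
            raise ValidationError("noise parameters must be non-negative")


@dataclass
class SceneParams:
    """Geometry and intensity parameters of a still multi-channel scene.

    Intensity defaults give membrane SNR ≈ 10 against shot + read noise;
    the acquisition geometry matches 80 nm/pixel sampling.
    """

    image_shape_px: Tuple[int, int] = (256, 256)
    pixel_size_nm: float = 80.0
    n_cells: int = 1
    cytoplasm_level: float = 20.0
    n_vesicles_per_cell: IntOrRange = 3
    vesicle_diameter_um_range: Tuple[float, float] = (1.2, 2.4)
    membrane_intensity: float = 200.0
    membrane_thickness_px: float = 2.0
    n_tubules_per_vesicle: IntOrRange = (0, 2)
    tubule_length_px_range: Tuple[int, int] = (8, 14)
    tubule_intensity_fold: float = 3.0
    dim_tubule_fold: float = 1.1
    bright_tubule_prob: float = 1.0
    nucleation_spot_fold: float = 2.0
    n_organelles: int = 10
    organelle_diameter_px_range: Tuple[int, int] = (3, 6)
    organelle_intensity: float = 150.0
    dextran_lumen_level: float = 50.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "vesicle_diameter_um_range",
            "tubule_length_px_range",
            "organelle_diameter_px_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValidationError(f"{name} must be an ordered positive range")
        for name in (
            "cytoplasm_level",
            "membrane_intensity",
            "dextran_lumen_level",
            "organelle_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.bright_tubule_prob <= 1:
            raise ValidationError("bright_tubule_prob must be in [0, 1]")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)
        # image must be large enough to host the requested cells
        if min(self.image_shape_px) < 32 * ceil(sqrt(self.n_cells)):
            raise ValidationError(
                "image too small for the requested number of cells"
            )


@dataclass
class TimelapseParams(SceneParams):
    """Scene parameters plus time-lapse dynamics.

    Vesicles are born at Poisson-distributed times at
    ``birth_rate_per_cell_per_min``; each independently succeeds
    (acquires the PtdIns3P marker ``marker_onset_frame_offset`` frames after
    birth and persists) with probability ``maturation_success_prob`` or
    fails (vanishes back into the plasma membrane after
    ``failure_lifetime_frames``).  A nascent-membrane marker follows a
    biphasic waveform peaking at ``biphasic_peak_frames`` after birth.
    """

    n_frames: int = 60
    frame_interval_s: float = 3.0
    birth_rate_per_cell_per_min: float = 2.0
    maturation_success_prob: float = 0.7
    marker_onset_frame_offset: int = 4
    biphasic_peak_frames: Tuple[int, int] = (2, 6)
    failure_lifetime_frames: int = 6
    motion_sigma_px: float = 0.3
    n_preexisting_per_cell: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if not 0 <= self.maturation_success_prob <= 1:
            raise ValidationError("maturation_success_prob must be in [0, 1]")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be positive")
        if self.birth_rate_per_cell_per_min < 0:
            raise ValidationError("birth rate must be >= 0")
        if self.failure_lifetime_frames < 1:
            raise ValidationError("failure_lifetime_frames must be >= 1")


# --------------------------------------------------------------------------
# ground-truth records
# --------------------------------------------------------------------------

@dataclass
class VesicleRecord:
    id: int
    cell_id: int
    center: Tuple[float, float]          # frame-0 / scene center
    radius_px: float
    diameter_um: float
    fate: str = "success"                # success | failure
    birth_frame: int = 0
    marker_onset_frame: Optional[int] = None
    present_at_start: bool = True
    present_frames: List[int] = field(default_factory=list)
    centers: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    lumen_dextran_sum: float = 0.0
    lumen_area_px: int = 0


@dataclass
class TubuleRecord:
    vesicle_id: int
    cell_id: int
    frame: int
    root: Tuple[float, float]
    angle_rad: float
    length_px: float
    is_bright: bool
    intensity_fold: float


@dataclass
class OrganelleRecord:
    id: int
    cell_id: int
    center: Tuple[float, float]
    area_px: int
    lumen_dextran_sum: float


@dataclass
class CellRecord:
    id: int
    center: Tuple[float, float]
    radius_px: float
    area_px: int


@dataclass
class GroundTruth:
    """Generative parameters and exact per-structure records of a render."""

    params: SceneParams
    cells: List[CellRecord]
    cell_masks: np.ndarray                       # (R, C) int labels
    vesicle_records: List[VesicleRecord]
    tubule_records: List[TubuleRecord]
    organelle_records: List[OrganelleRecord]
    noise_free_channels: np.ndarray              # same shape as stack pixels
    vesicle_masks: Optional[np.ndarray] = None   # scene only: (R, C) labels
    organelle_masks: Optional[np.ndarray] = None
    channel_names: List[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        def _rec(x):
            d = dataclasses.asdict(x)
            for k, v in list(d.items()):
                if isinstance(v, dict):
                    d[k] = {str(kk): list(vv) if isinstance(vv, tuple) else vv
                            for kk, vv in v.items()}
            return d

        params = dataclasses.asdict(self.params)
        return {
            "params": params,
            "channel_names": self.channel_names,
            "cells": [_rec(c) for c in self.cells],
            "vesicles": [_rec(v) for v in self.vesicle_records],
            "tubules": [_rec(t) for t in self.tubule_records],
            "organelles": [_rec(o) for o in self.organelle_records],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# low-level rendering primitives
# --------------------------------------------------------------------------

def _patch(shape: Tuple[int, int], center: Tuple[float, float], extent: float):
    """Bounding-box slices plus local coordinate grids around ``center``."""
    r0 = max(0, int(np.floor(center[0] - extent)))
    r1 = min(shape[0], int(np.ceil(center[0] + extent)) + 1)
    c0 = max(0, int(np.floor(center[1] - extent)))
    c1 = min(shape[1], int(np.ceil(center[1] + extent)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), rr.astype(float), cc.astype(float)


def add_ring(img: np.ndarray, center, radius: float, sigma: float,
             amplitude: float) -> None:
    """Additively render an annulus with Gaussian radial cross-section."""
    sl, rr, cc = _patch(img.shape, center, radius + 4 * sigma)
    d = np.hypot(rr - center[0], cc - center[1])
    img[sl] += amplitude * np.exp(-0.5 * ((d - radius) / sigma) ** 2)


def add_blob(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    sl, rr, cc = _patch(img.shape, center, 4 * sigma)
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    img[sl] += amplitude * np.exp(-0.5 * d2 / sigma**2)


def add_segment(img: np.ndarray, p0, p1, sigma: float, amplitude: float) -> None:
    """Additively render a line segment with Gaussian cross-section."""
    lo = (min(p0[0], p1[0]), min(p0[1], p1[1]))
    hi = (max(p0[0], p1[0]), max(p0[1], p1[1]))
    center = ((lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2)
    extent = max(hi[0] - lo[0], hi[1] - lo[1]) / 2 + 4 * sigma
    sl, rr, cc = _patch(img.shape, center, extent)
    v = np.array([p1[0] - p0[0], p1[1] - p0[1]])
    L2 = float(v @ v)
    wr, wc = rr - p0[0], cc - p0[1]
    if L2 == 0:
        d = np.hypot(wr, wc)
    else:
        t = np.clip((wr * v[0] + wc * v[1]) / L2, 0.0, 1.0)
        d = np.hypot(wr - t * v[0], wc - t * v[1])
    img[sl] += amplitude * np.exp(-0.5 * (d / sigma) ** 2)


def disc_mask(shape: Tuple[int, int], center, radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius`` of center."""
    out = np.zeros(shape, dtype=bool)
    sl, rr, cc = _patch(shape, center, radius + 1)
    out[sl] = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return out


def add_noise(image: np.ndarray, poisson_scale: float, read_sigma: float,
              seed: int) -> np.ndarray:
    """Poisson shot noise plus Gaussian read noise, clamped at zero.

    Each pixel is drawn ``Poisson(pixel × poisson_scale) / poisson_scale``
    (``poisson_scale = 0`` disables shot noise) plus ``N(0, read_sigma²)``.
    Deterministic per seed.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)) or np.any(image < 0):
        raise ValidationError("image must be finite and non-negative")
    if poisson_scale < 0 or read_sigma < 0:
        raise ValidationError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    out = image.copy()
    if poisson_scale > 0:
        out = rng.poisson(image * poisson_scale).astype(float) / poisson_scale
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=image.shape)
    return np.clip(out, 0.0, None)


# --------------------------------------------------------------------------
# layout helpers
# --------------------------------------------------------------------------

def _sample_count(rng: np.random.Generator, spec: IntOrRange) -> int:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _layout_cells(params: SceneParams, rng: np.random.Generator):
    rows, cols = params.image_shape_px
    n = params.n_cells
    g_c = ceil(sqrt(n))
    g_r = ceil(n / g_c)
    pitch_r, pitch_c = rows / g_r, cols / g_c
    radius = 0.42 * min(pitch_r, pitch_c)
    cells: List[CellRecord] = []
    masks = np.zeros((rows, cols), dtype=np.int32)
    k = 0
    for i in range(g_r):
        for j in range(g_c):
            if k >= n:
                break
            jitter = rng.uniform(-0.04, 0.04, size=2)
            cr = (i + 0.5 + jitter[0]) * pitch_r
            cc_ = (j + 0.5 + jitter[1]) * pitch_c
            mask = disc_mask((rows, cols), (cr, cc_), radius)
            k += 1
            masks[mask] = k
            cells.append(CellRecord(id=k, center=(cr, cc_), radius_px=radius,
                                    area_px=int(mask.sum())))
    return cells, masks


def _place_disc(rng, cell: CellRecord, margin: float,
                existing: List[Tuple[Tuple[float, float], float]],
                radius: float, clearance: float, retries: int = 500):
    """Random center inside the cell, ``margin`` from its edge and
    ``clearance`` beyond touching any existing disc."""
    reach = cell.radius_px - margin
    if reach <= 0:
        raise GenerationError(
            "cell too small for the requested structures (infeasible packing)"
        )
    for _ in range(retries):
        ang = rng.uniform(0, 2 * pi)
        rad = reach * sqrt(rng.uniform())
        cand = (cell.center[0] + rad * sin(ang), cell.center[1] + rad * cos(ang))
        ok = all(
            np.hypot(cand[0] - c0[0], cand[1] - c0[1]) > radius + r0 + clearance
            for c0, r0 in existing
        )
        if ok:
            return cand
    raise GenerationError(
        "could not place structure without overlap after bounded retries"
    )


def _band_mean_factor(sigma: float, width_px: int = 3) -> float:
    """Mean of the unit Gaussian cross-section over a centered width_px band."""
    offs = np.arange(width_px) - (width_px - 1) / 2
    return float(np.mean(np.exp(-0.5 * (offs / sigma) ** 2)))


# --------------------------------------------------------------------------
# scene rendering
# --------------------------------------------------------------------------

def render_scene(params: SceneParams) -> Tuple[ImageStack, GroundTruth]:
    """Render one still multi-channel scene.

    Channels: ``membrane`` (vesicle rings + tubules + nucleation spots),
    ``secondary`` (tubule-enriched marker), ``organelle`` (puncta),
    ``dextran`` (lumen fill over cytoplasm), ``pm`` (cell outline).
    Deterministic given ``params.seed``; noise is applied last and the
    returned :class:`GroundTruth` matches the noise-free render exactly.
    """
    rows, cols = params.image_shape_px
    ss = np.random.SeedSequence(params.seed)
    rng_layout, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    sigma = params.membrane_thickness_px / 2.355  # FWHM -> Gaussian sigma

    img = np.zeros((len(SCENE_CHANNELS), rows, cols), dtype=np.float64)
    ch = {name: img[i] for i, name in enumerate(SCENE_CHANNELS)}

    cells, cell_masks = _layout_cells(params, rng_layout)
    inside = cell_masks > 0
    for name in ("membrane", "secondary", "dextran"):
        ch[name][inside] += params.cytoplasm_level
    for cell in cells:
        add_ring(ch["pm"], cell.center, cell.radius_px, sigma,
                 params.membrane_intensity)

    px_per_um = 1000.0 / params.pixel_size_nm
    tub_lo, tub_hi = params.tubule_length_px_range
    vesicle_records: List[VesicleRecord] = []
    tubule_records: List[TubuleRecord] = []
    vesicle_masks = np.zeros((rows, cols), dtype=np.int32)
    placed: Dict[int, List[Tuple[Tuple[float, float], float]]] = {
        c.id: [] for c in cells
    }
    vid = 0
    for cell in cells:
        n_ves = _sample_count(rng_layout, params.n_vesicles_per_cell)
        for _ in range(n_ves):
            vid += 1
            d_um = rng_layout.uniform(*params.vesicle_diameter_um_range)
            r_px = d_um * px_per_um / 2
            margin = r_px + tub_hi + 3
            center = _place_disc(rng_layout, cell, margin, placed[cell.id],
                                 r_px, clearance=tub_hi + 4)
            placed[cell.id].append((center, r_px))
            add_ring(ch["membrane"], center, r_px, sigma,
                     params.membrane_intensity)
            # lumen: dextran replaces cytoplasm inside the ring
            lumen_r = max(1.0, r_px - 2 * sigma - 1)
            lum = disc_mask((rows, cols), center, lumen_r)
            ch["dextran"][lum] = params.dextran_lumen_level
            footprint = disc_mask((rows, cols), center, r_px)
            vesicle_masks[footprint] = vid
            rec = VesicleRecord(
                id=vid, cell_id=cell.id, center=center, radius_px=r_px,
                diameter_um=d_um,
                lumen_dextran_sum=params.dextran_lumen_level * int(lum.sum()),
                lumen_area_px=int(lum.sum()),
                present_frames=[0], centers={0: center},
            )
            vesicle_records.append(rec)
            # tubules, radially outward with jittered angle
            n_tub = _sample_count(rng_layout, params.n_tubules_per_vesicle)
            base = rng_layout.uniform(0, 2 * pi)
            for t in range(n_tub):
                ang = base + t * (2 * pi / max(n_tub, 1)) \
                    + rng_layout.uniform(-0.3, 0.3)
                length = float(rng_layout.integers(tub_lo, tub_hi + 1))
                root = (center[0] + r_px * sin(ang), center[1] + r_px * cos(ang))
                tip = (center[0] + (r_px + length) * sin(ang),
                       center[1] + (r_px + length) * cos(ang))
                add_segment(ch["membrane"], root, tip, sigma,
                            params.membrane_intensity)
                add_blob(ch["membrane"], root, 1.5 * sigma,
                         (params.nucleation_spot_fold - 1)
                         * params.membrane_intensity)
                bright = bool(rng_layout.uniform() < params.bright_tubule_prob)
                fold = (params.tubule_intensity_fold if bright
                        else params.dim_tubule_fold)
                # amplitude chosen so the 3-px band mean over the tubule
                # reads `fold` × cytoplasm in the secondary channel
                amp = ((fold - 1) * params.cytoplasm_level
                       / _band_mean_factor(sigma))
                add_segment(ch["secondary"], root, tip, sigma, amp)
                tubule_records.append(TubuleRecord(
                    vesicle_id=vid, cell_id=cell.id, frame=0, root=root,
                    angle_rad=ang, length_px=length, is_bright=bright,
                    intensity_fold=fold,
                ))

    organelle_records: List[OrganelleRecord] = []
    organelle_masks = np.zeros((rows, cols), dtype=np.int32)
    oid = 0
    for k in range(params.n_organelles):
        oid += 1
        cell = cells[k % len(cells)]
        d_px = rng_layout.uniform(*params.organelle_diameter_px_range)
        r_o = d_px / 2
        center = _place_disc(rng_layout, cell, r_o + 2, placed[cell.id],
                             r_o, clearance=2)
        placed[cell.id].append((center, r_o))
        m = disc_mask((rows, cols), center, r_o)
        ch["organelle"][m] += params.organelle_intensity
        ch["dextran"][m] = params.dextran_lumen_level
        organelle_masks[m] = oid
        organelle_records.append(OrganelleRecord(
            id=oid, cell_id=cell.id, center=center, area_px=int(m.sum()),
            lumen_dextran_sum=params.dextran_lumen_level * int(m.sum()),
        ))

    noise_free = img[None].copy()
    noisy = np.empty_like(noise_free)
    noise_seed = int(rng_noise.integers(0, 2**31 - 1))
    for c in range(img.shape[0]):
        noisy[0, c] = add_noise(img[c], params.noise.poisson_scale,
                                params.noise.read_sigma, noise_seed + c)

    stack = ImageStack(
        pixels=noisy, axis_kind="time", pixel_size_nm=params.pixel_size_nm,
        channel_names=list(SCENE_CHANNELS),
    )
    gt = GroundTruth(
        params=params, cells=cells, cell_masks=cell_masks,
        vesicle_records=vesicle_records, tubule_records=tubule_records,
        organelle_records=organelle_records, noise_free_channels=noise_free,
        vesicle_masks=vesicle_masks, organelle_masks=organelle_masks,
        channel_names=list(SCENE_CHANNELS),
    )
    return stack, gt


# --------------------------------------------------------------------------
# time-lapse rendering
# --------------------------------------------------------------------------

def _biphasic_waveform(t: np.ndarray, peaks: Tuple[int, int]) -> np.ndarray:
    """Two-peaked recruitment waveform; the first peak is the global maximum."""
    p1, p2 = peaks
    s = max(1.0, (p2 - p1) / 3.0)
    w = np.exp(-0.5 * ((t - p1) / s) ** 2) + 0.7 * np.exp(-0.5 * ((t - p2) / s) ** 2)
    return np.where(t >= 0, w, 0.0)


def render_timelapse(params: TimelapseParams) -> Tuple[ImageStack, GroundTruth]:
    """Render a time-lapse with vesicle births, maturation and failure.

    Channels: ``pm`` (plasma-membrane band + vesicle rings while present),
    ``marker`` (PtdIns3P marker, acquired by successful vesicles
    ``marker_onset_frame_offset`` frames after birth), ``nascent``
    (biphasic recruitment marker on young vesicles).
    """
    rows, cols = params.image_shape_px
    T = params.n_frames
    ss = np.random.SeedSequence(params.seed)
    rng_layout, rng_noise, rng_dyn = [np.random.default_rng(s) for s in ss.spawn(3)]
    sigma = params.membrane_thickness_px / 2.355
    px_per_um = 1000.0 / params.pixel_size_nm

    cells, cell_masks = _layout_cells(params, rng_layout)
    inside = cell_masks > 0

    # --- vesicle population --------------------------------------------
    rate_per_frame = (params.birth_rate_per_cell_per_min
                      * params.frame_interval_s / 60.0)
    vesicle_records: List[VesicleRecord] = []
    # (center, radius, first_frame, last_frame) per cell, so placement only
    # avoids vesicles that are co-resident in time
    placed: Dict[int, List[Tuple[Tuple[float, float], float, int, int]]] = {
        c.id: [] for c in cells
    }
    # worst-case random-walk excursion, to keep co-resident vesicles apart
    drift = 2.0 * params.motion_sigma_px * sqrt(T) + 2.0
    vid = 0

    def _new_vesicle(cell: CellRecord, birth: int, preexisting: bool):
        nonlocal vid
        vid += 1
        d_um = rng_dyn.uniform(*params.vesicle_diameter_um_range)
        r_px = d_um * px_per_um / 2
        margin = r_px + 4
        reach = cell.radius_px - margin
        success = bool(rng_dyn.uniform() < params.maturation_success_prob)
        if preexisting:
            fate, onset = "success", 0
            last = T - 1
        elif success:
            fate = "success"
            onset = birth + params.marker_onset_frame_offset
            last = T - 1
        else:
            fate, onset = "failure", None
            last = min(T - 1, birth + params.failure_lifetime_frames)
        coresident = [(c0, r0) for c0, r0, f0, f1 in placed[cell.id]
                      if not (f1 < birth or f0 > last)]
        center = _place_disc(rng_dyn, cell, margin, coresident,
                             r_px, clearance=drift)
        placed[cell.id].append((center, r_px, birth, last))
        frames = list(range(birth, last + 1))
        centers = {}
        pos = np.array(center, dtype=float)
        for f in frames:
            centers[f] = (float(pos[0]), float(pos[1]))
            step = rng_dyn.normal(0.0, params.motion_sigma_px, size=2)
            pos = pos + step
            # reflect to stay inside the cell
            off = pos - np.array(cell.center)
            d = np.hypot(*off)
            if d > reach > 0:
                pos = np.array(cell.center) + off * (reach / d)
        vesicle_records.append(VesicleRecord(
            id=vid, cell_id=cell.id, center=center, radius_px=r_px,
            diameter_um=d_um, fate=fate, birth_frame=birth,
            marker_onset_frame=onset, present_at_start=(birth == 0),
            present_frames=frames, centers=centers,
        ))

    for cell in cells:
        for _ in range(params.n_preexisting_per_cell):
            _new_vesicle(cell, 0, preexisting=True)
        births = rng_dyn.poisson(rate_per_frame, size=T)
        for f in range(T):
            for _ in range(births[f]):
                _new_vesicle(cell, f, preexisting=False)

    # --- rendering -------------------------------------------------------
    nf = np.zeros((T, len(TIMELAPSE_CHANNELS), rows, cols), dtype=np.float32)
    for f in range(T):
        pm, marker, nascent = nf[f]
        pm[inside] += params.cytoplasm_level * 0.25
        marker[inside] += params.cytoplasm_level
        nascent[inside] += params.cytoplasm_level
        for cell in cells:
            add_ring(pm, cell.center, cell.radius_px, sigma,
                     params.membrane_intensity)
    for rec in vesicle_records:
        for f in rec.present_frames:
            pm, marker, nascent = nf[f]
            c = rec.centers[f]
            add_ring(pm, c, rec.radius_px, sigma, params.membrane_intensity)
            if rec.marker_onset_frame is not None and f >= rec.marker_onset_frame:
                add_ring(marker, c, rec.radius_px, sigma,
                         params.membrane_intensity)
            age = f - rec.birth_frame
            w = float(_biphasic_waveform(np.array([age], dtype=float),
                                         params.biphasic_peak_frames)[0])
            if w > 1e-3:
                add_ring(nascent, c, rec.radius_px, sigma,
                         params.membrane_intensity * w)

    noise_free = nf.astype(np.float32)
    noisy = np.empty(nf.shape, dtype=np.float64)
    base = int(rng_noise.integers(0, 2**31 - 1 - T * 8))
    for f in range(T):
        for c in range(nf.shape[1]):
            noisy[f, c] = add_noise(nf[f, c].astype(float),
                                    params.noise.poisson_scale,
                                    params.noise.read_sigma,
                                    base + f * nf.shape[1] + c)

    stack = ImageStack(
        pixels=noisy, axis_kind="time", pixel_size_nm=params.pixel_size_nm,
        frame_interval_s=params.frame_interval_s,
        channel_names=list(TIMELAPSE_CHANNELS),
    )
    gt = GroundTruth(
        params=params, cells=cells, cell_masks=cell_masks,
        vesicle_records=vesicle_records, tubule_records=[],
        organelle_records=[], noise_free_channels=noise_free,
        channel_names=list(TIMELAPSE_CHANNELS),
    )
    return stack, gt


def as_zstack(stack: ImageStack, focus_index: int, n_planes: int,
              blur_step_px: float = 1.0, z_step_nm: float = 250.0,
              seed: Optional[int] = None,
              noise: Optional[NoiseParams] = None) -> ImageStack:
    """Expand a single-frame scene into a defocus z-stack.

    Plane ``i`` is the in-focus frame blurred with a Gaussian of
    ``blur_step_px × |i − focus_index|``; one in-focus plane per stack.
    Optionally re-applies noise per plane.
    """
    from scipy.ndimage import gaussian_filter

    if stack.n_frames != 1:
        raise ValidationError("as_zstack expects a single-frame scene")
    if not 0 <= focus_index < n_planes:
        raise ValidationError("focus_index must lie within the stack")
    base = stack.pixels[0]
    planes = np.empty((n_planes, *base.shape), dtype=np.float64)
    for i in range(n_planes):
        s = blur_step_px * abs(i - focus_index)
        for c in range(base.shape[0]):
            planes[i, c] = base[c] if s == 0 else gaussian_filter(base[c], s)
    if noise is not None and seed is not None:
        for i in range(n_planes):
            for c in range(base.shape[0]):
                planes[i, c] = add_noise(planes[i, c], noise.poisson_scale,
                                         noise.read_sigma,
                                         seed + i * base.shape[0] + c)
    return ImageStack(
        pixels=planes, axis_kind="z", pixel_size_nm=stack.pixel_size_nm,
        z_step_nm=z_step_nm, channel_names=list(stack.channel_names),
    )
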