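# Methods

This note documents the models, conventions and parameter choices behind
each analysis stage, what the synthetic data generator does and does not
emulate, and the numerical decisions a user may want to revisit.

## Conventions

All coordinates are 0-based `(row, col)` with pixel centers at integer
coordinates.  Intensities are converted to float64 on load; saturation is
not modeled, since every measurement is a mean or sum statistic.  Time-lapse
and z-stack data share one container (`ImageStack`) distinguished by
`axis_kind`, because all pixel-level operations are identical.  Default
physical calibration is 80 nm/pixel laterally, 3 s between frames and
250 nm between z-planes.

## Analysis configuration

`AnalysisConfig` collects every tunable parameter.  The defaults encode the
analysis conventions the pipeline was designed around:

| parameter | default | meaning |
|---|---|---|
| `min_structure_area_px` | 5 | smallest segmentable structure (inclusive) |
| `tubule_min_length_px` | 6 | a tubule must *exceed* this skeleton length |
| `positive_fold_threshold` | 1.5 | tubule positivity vs background, inclusive |
| `background_square_px` | 100 | side of the cytoplasmic background square |
| `profile_exclusion_window_px` | 15 (odd) | window excluded from profile background |
| `profile_width_px` | 3 | band width of line/contour profiles |
| `min_macropinosome_diameter_um` | 1.0 | CV analysis includes vesicles above this |
| `membrane_roi_diameter_px` | 10 | circular ROI for membrane time traces |
| `trace_align_time_s` | 15 | trace peak-alignment timepoint |
| `min_track_radius_nm` | 400 | tracks below this median radius are excluded |
| `max_displacement_nm` | 1600 | linking gate (≈ two vesicle radii) |
| `max_gap` | 2 | frames a track may go undetected |
| `success_fold_threshold`, `success_min_frames` | 1.5, 2 | maturation call |
| `cv_ddof` | 1 | CV uses the sample SD; set 0 for population |

Segmentation thresholds default to Otsu with an `absolute_threshold`
override; automated thresholding replaces a manual/unspecified step, so the
method is explicit and configurable.  Under Otsu, foreground is strictly
above the threshold; under an absolute threshold the boundary is inclusive.

## Segmentation and per-experiment normalization

Structures are 8-connected components above threshold with area ≥ 5 px,
relabeled consecutively.  8-connectivity is the robust choice for small
puncta; "at least five pixels" is read as an inclusive bound.  Structure
means/sums carry no implicit background subtraction: adding a constant *c*
to a channel raises every mean by exactly *c*.  Per-experiment
normalization divides each value by the mean of all values in its
experiment, making the per-experiment mean exactly 1 and cancelling any
multiplicative gain (staining, acquisition settings).  Structures are
pooled per image unless a cell mask is supplied; watershed splitting of
touching organelles is out of scope.

## Membrane contours and the CV tubulation statistic

The contour of a segmented vesicle is the iso-level-0.5 boundary of its
hole-filled mask (marching squares), resampled to ~1 px arc-length spacing,
traversed counter-clockwise from the boundary point nearest the image
origin (the CV is order-invariant, but profiles must be reproducible).
Because a thresholded boundary sits on the outer flank of the membrane
cross-section, `snap_contour_to_ridge` then moves each point along its
local normal to the intensity maximum within ±3 px (0.25-px sub-pixel grid,
light circular smoothing).  Profiling the ridge rather than the flank is
what makes the circumference signal flat on a plain ring (CV ≈ 0.015 in
noise-free renders) and strongly modulated by tubule-nucleation spots
(CV ≈ 0.3), giving the statistic its dynamic range.

Profiles average `profile_width_px` bilinear samples spaced 1 px along the
local normal.  Samples whose band leaves the image are flagged missing.
The vesicle diameter is the equivalent-circle diameter
`2·sqrt(area/π)·pixel_size_nm/1000` of the filled mask; only vesicles with
diameter > 1 µm enter the CV analysis.  The CV is computed on raw (not
normalized) intensities — it is invariant to gain, so the choice only
matters in the presence of additive offsets.  The SD convention is sample
(n−1); `cv_ddof = 0` switches to the population convention.

## Tubule detection and positivity

Tubules are protrusions of the vesicle mask: the hole-filled mask minus a
disc model of the vesicle body (center at the distance-transform peak,
radius the median center-to-boundary distance).  Root and tip of a
protrusion then sit at the same threshold iso-level, so threshold-dependent
offsets cancel, and the tubule length — the maximal Euclidean reach of the
protrusion beyond the body — is unbiased to about ±1 px on rendered
tubules.  Components reaching ≤ 2 px are discarded as rasterization
slivers.  Each protrusion is skeletonized and its main path ordered from
the root by a Dijkstra geodesic (diagonal steps √2), robust to short side
branches.  Detections must *exceed* 6 px (an 8 px tubule is detected with
recall/precision ≥ 0.95 at SNR ≥ 5; a 5 px stub is rejected).

Tubule signal is the mean over the skeleton dilated to the 3-px profile
band width, for consistency with the profile convention.  A tubule is
positive when signal ≥ 1.5 × cytoplasmic background, **boundary
inclusive** ("at least 50% above background").  The background is the mean
of a 100×100 px square placed inside the cell and off all segmented
structures — one square per cell; auto-placement raster-scans
deterministically and fails loudly when no valid placement exists.  The
per-cell positive fraction treats each cell as a single biological data
point; a cell with zero tubules yields a missing fraction rather than 0.

## Cross-tubule profile alignment

Line profiles across tubules are aligned by whole-sample shifts so the
reference-channel maximum (ties → first occurrence along the drawn
direction) lands at the common center index; shifted-out samples are
missing, never wrapped — a tubule cross-section is not periodic.  Each
profile's per-channel background is the mean of its samples outside the
centered 15-px exclusion window, and all channels are divided by their own
background, so values read as fold change over cytoplasm and the off-window
mean of every normalized profile is exactly 1.  The aggregate is the
per-position mean with a t-based 95% CI over however many profiles are
non-missing there (per-position n reported; CI undefined at n = 1).
Aligning already-aligned profiles is the identity.

## Membrane time traces

A trace samples every channel in a circular ROI (pixels whose centers lie
within diameter/2 of the mark) following annotated membrane points over
consecutive frames; an ROI partially outside the image yields a missing
sample.  Traces are normalized per channel to their own time-series mean
(idempotent), then shifted by whole samples so the reference-channel peak
(ties → earliest; optionally restricted to an annotated nascent window)
lands at the sample whose time equals 15 s — index 5 at 3 s spacing.  Only
whole-sample shifts are used because the alignment point is an acquisition
timepoint; no interpolation is performed.  Traces of unequal length are
aggregated with all available samples per timepoint and per-timepoint n
reported.  The no-alignment variant (`align=False`) serves conditions in
which the reference marker is pharmacologically removed and has no peak.

## Tracking and maturation

Detections are per-frame segmentations of the vesicle marker channel.  A
membrane marker labels the limiting membrane, so a thresholded vesicle is
an annulus; the detection's equivalent radius `sqrt(area/π)·pixel_size` is
computed from the membrane-enclosed area, estimated as the mean of the
outer (hole-filled) and inner (hole) areas — this recovers the
membrane-centerline circle and makes measured diameters track generative
diameters to ~0.03 µm.  Solid structures fall back to their plain area.

Linking is greedy mutual-nearest-neighbour: in each frame, open tracks and
detections are matched by repeatedly pairing the mutually closest pair
within 1600 nm (≈ two vesicle radii); unmatched detections start new
tracks; a track may bridge up to 2 missing frames, with the same flat
distance gate (a vanished vesicle may only be resumed where it
disappeared).  This is deliberately simpler than a full linear-assignment
tracker: at macropinosome densities the reported quantities (diameter,
frequency, fate) are insensitive to linker details, and the greedy
assignment is order-invariant and transparent.  On synthetic movies with
20 vesicles over 100 frames it recovers ≥ 95% of tracks unbroken.

Newly formed macropinosomes are tracks with median equivalent radius
≥ 400 nm that were *not* present in the first frame.  Diameter is 2 × the
median radius over the track; frequency is accepted tracks per cell per
minute of movie duration.  Maturation fate follows the marker mean over
each detection's membrane pixels: success when it exceeds 1.5 × cytoplasmic
background for ≥ 2 consecutive frames (both constants are calibration
choices, configurable); failure when the track instead ends before the
movie does — a vesicle tracked by the plasma-membrane marker that
disappears has re-fused with the plasma membrane; censored when the movie
ends first.  Censored tracks are excluded from the success-rate denominator
(their fate is unknown).

## Fluid-phase cargo

Whole-cell dextran is measured on the pixelwise sum projection of a
z-stack: in-mask total minus (background-square mean × in-mask pixel
count), with the square required to lie outside all cells.  Negative totals
are deliberately not clamped — clamping would bias per-experiment averages.
Organelle-associated dextran uses the most in-focus plane, chosen by
normalized variance (variance/mean², a standard autofocus criterion; ties
→ lowest index), segments organelles of ≥ 5 px from their marker channel
inside the cell mask, and sums dextran over all organelle pixels.  The
≈ 240 nm diffraction limit motivates the 5-px minimum; no separate
size filter is applied.  Pearson colocalization is the standard correlation
over in-mask pixel pairs and is undefined (an error) when a channel is
constant within the mask.

## Nested statistics

`nested_summary` implements superplot aggregation: per-cell values average
into per-experiment means, each experiment contributes one unweighted
point, and the report is the grand mean with a t-based 95% CI across
experiments (undefined at n = 1).  Unweighted means match the convention of
plotting one point per experiment regardless of cell count; a `pooled`
flag covers analyses that instead pool individual structures.  Under a
simulated global null (3 experiments × 20 cells, standard normal) the CI
covers the true mean in 95% ± 2% of replicates.  `holm_sidak` is the
step-down Šidák adjustment — sorted ascending,
`adj_i = max_{j≤i}(1 − (1 − p_(j))^(m−j+1))` clamped at 1, rejection when
the adjusted value is below α — implemented directly from this definition
and cross-checked against `statsmodels.stats.multitest.multipletests`
(`method="holm-sidak"`) in the tests.  Two-group t-tests and one-way ANOVA
are thin scipy wrappers provided for convenience.

## Synthetic scenes

The generator emulates the statistical structure the analyses assume, not
optics: cells are non-overlapping discs on a jittered grid; membranes
(vesicle rings, tubules, plasma-membrane band) have a Gaussian
cross-section whose FWHM is `membrane_thickness_px` (default 2 px at
80 nm/px); tubules are straight segments rooted on the ring, radially
outward with jittered angles, with a bright nucleation spot at the root;
organelle puncta and all lumenal dextran fills are *hard* pixel masks with
constant level, so ground-truth sums are exact (level × pixel count), with
lumen dextran replacing the cytoplasm level.  The secondary (tubule-marker)
channel renders each tubule with an amplitude calibrated so its mean over
the 3-px band equals the requested fold over cytoplasm, making classifier
ground truth exact.  Noise is Poisson shot noise
(`Poisson(pixel·scale)/scale`; scale 0 disables) plus Gaussian read noise,
applied last and clamped at zero.  Default intensities (cytoplasm 20,
membrane 200, read σ 2, Poisson scale 1) give membrane SNR ≈ 10; the
channel intensity statistics of the original imaging are not published, so
these are chosen for comfortable SNR and are fully configurable.

Time-lapses add vesicle births as a per-frame Poisson process
(`birth_rate_per_cell_per_min`, default 2), independent Bernoulli
maturation (`maturation_success_prob`), marker onset a fixed number of
frames after birth for successes, disappearance after
`failure_lifetime_frames` for failures, a two-peak recruitment waveform on
the nascent-marker channel (first peak global maximum), and per-frame
Gaussian random-walk motion reflected at the cell boundary.  Co-resident
vesicles are placed with clearance for their worst-case drift; infeasible
packing raises an error rather than degrading silently.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: diffraction (no PSF beyond the Gaussian
cross-section), photobleaching, focal drift, irregular cell and vesicle
shapes, fission/fusion events, and 3-D structure (z-stacks are defocus
blurs of a single in-focus plane).  Ground-truth recovery here validates
the estimators' correctness, not their robustness to every real-world
artifact.

Determinism: each render draws from sub-streams (layout, noise, dynamics)
spawned from a single seed, so scenes are bit-reproducible per seed and
ground-truth JSON files are byte-identical across runs.

## Problem sizes used in validation

The test suite and the acceptance script validate on scenes of 256²–576²
pixels with 1–4 cells, time-lapses of 40–100 frames, 10–20 seeds per
stochastic property, and 1000 replicates for CI coverage — sizes at which
every statistical check has adequate power while the whole suite completes
in a few minutes.

## Known limitations

- The tracker is greedy; at densities far above those simulated (many
  vesicles per cell radius) a LAP-style global assignment would be needed.
- Maturation-call constants (1.5×, 2 frames) mirror the tubule-positivity
  convention; they are calibration choices, not measured quantities.
- Tubule detection assumes roughly circular vesicle bodies; strongly
  elliptical structures would need a fitted body model.
- One background square per cell is used; background inhomogeneity within
  a cell is not modeled.
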