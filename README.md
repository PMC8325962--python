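# pinoquant

Quantitative image analysis of macropinosome membranes in fluorescence
microscopy, built for studies of membrane recycling from macropinosomes:
how often macropinosomes form and mature, how strongly recycling machinery
is recruited to their limiting membrane, whether membrane tubules carry a
marker of interest, and how much fluid-phase cargo (dextran) cells retain.

The package bundles the quantification steps such a study needs as one
tested pipeline, together with a synthetic scene generator that renders
multi-channel cells with exact ground truth — so every analysis can be
validated against known generative parameters before being pointed at real
data.

## What it computes

- **Structure segmentation and measurement** — marker-positive structures of
  at least 5 px (8-connected, Otsu or absolute threshold), per-structure
  mean/sum intensity in any channel, and per-experiment normalization
  (each value divided by its experiment mean, removing staining and
  acquisition gain).
- **Membrane-contour profiling** — sub-pixel closed contours around each
  macropinosome, refined onto the membrane intensity ridge, sampled with a
  3-px-wide band; the **coefficient of variation** CV = s/x̄ (sample SD over
  mean) of intensity along the circumference of vesicles > 1 µm in diameter,
  a scalar proxy for tubule nucleation.
- **Tubule detection and classification** — protrusions longer than 6 px
  (80 nm/px) found by morphological body subtraction and skeletonized; each
  tubule called positive when its mean signal ≥ 1.5 × cytoplasmic background
  (mean of a 100×100 px square), reported as a per-cell positive fraction.
- **Cross-tubule profiles** — line profiles aligned on the reference-channel
  peak and expressed as fold change over the local background (mean outside
  a 15-px window), aggregated as mean ± t-based 95% CI.
- **Membrane time traces** — a 10-px circular ROI following the limiting
  membrane over time, normalized to the trace mean and peak-aligned at 15 s
  (3 s frame interval), aggregated across vesicles.
- **Macropinosome tracking** — per-frame detection, greedy mutual-nearest-
  neighbour linking with gap closing, exclusion of structures with radius
  < 400 nm or present at movie start, per-track diameters (2 × median
  equivalent radius), formation frequency (events/cell/min), and maturation
  fate (success = PtdIns3P-marker acquisition; failure = re-fusion with the
  plasma membrane; censored = movie ends first).
- **Fluid-phase cargo** — sum-projected whole-cell dextran minus background
  (100×100 px square outside cells), organelle-associated dextran on the
  most in-focus plane, masked Pearson colocalization.
- **Statistics** — superplot-style nested summaries (cells → experiment
  means → grand mean ± 95% CI across experiments) and step-down Šidák
  (Holm–Šidák) multiple-comparison adjustment.

## Worked example

Render a synthetic time-lapse, track macropinosomes and summarize:

```bash
pinoquant simulate --out sim --seed 11 --timelapse --n-frames 40
pinoquant track --image sim/scene.tif --out trk --marker-channel pm --n-cells 1
pinoquant summarize --measurements trk/track_metrics.csv --out summ
cat summ/summary.csv
```

which prints

```
metric_name,grand_mean,ci_half_width_95,n_experiments
diameter_um,1.0960455477194753,,1
frequency_per_cell_per_min,2.5641025641025643,,1
```

`diameter_um` is the mean diameter of newly formed macropinosomes (µm,
2 × median equivalent radius over each track) and
`frequency_per_cell_per_min` their formation rate; with a single simulated
experiment the across-experiment CI is undefined and left empty.  The
`manifest.json` written next to each output logs the configuration echo,
seed, package versions and the counts entering/leaving every filter (e.g.
how many tracks the 400 nm rule removed), so any run is reproducible from
its manifest.

The same pipeline is available as a library:

```python
import pinoquant as pq
from pinoquant import tracking

cfg = pq.AnalysisConfig(threshold_method="absolute", absolute_threshold=60.0)
stack, truth = pq.render_timelapse(pq.TimelapseParams(seed=11, n_frames=40))
dets = tracking.detect_per_frame(stack, "pm", cfg)
tracks = tracking.link_tracks(dets, cfg.max_displacement_nm, cfg.max_gap,
                              stack.pixel_size_nm)
new = tracking.filter_new_tracks(tracks, cfg)
fates = [tracking.classify_maturation(t, stack, "marker", "pm",
                                      background=20.0, config=cfg)
         for t in new]
print(tracking.success_fraction(fates))
```

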