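# pillartrack

Contractile force analysis of engineered heart tissues (EHTs) from
brightfield video, for labs running pillar-based heart-on-chip
platforms.

EHTs are 3-D cardiac micro-tissues that self-assemble around two
elastic pillars and beat spontaneously or under pacing.  Because each
pillar is a linear spring, the beat can be read out optically: track
the bright, transparent pillar tips in every frame, measure the
inter-tip distance, and convert its deflection δ to absolute force
with the pillar stiffness k,

    F = k · δ/2,      k = 6 E I / (a² (3L − a)),

the Euler–Bernoulli cantilever stiffness for a point load at the
tissue-attachment height *a* with the deflection observed at the tip
(I = πD⁴/64 for circular cross-sections, w·b³/12 for rectangular; the
factor ½ shares the gap change between the two pillars).  On top of
the force trace, the package extracts per-cycle contractile kinetics —
peak force, beating frequency, T10/T90 upstroke and decay times,
contraction and relaxation velocities — and the tissue surface area
per frame for force-per-area normalization.

The per-frame detection chain is: grayscale → bilateral smoothing →
morphological opening → Otsu binarization → per-half nearest-area
contour selection → subpixel moment centroids, with a dedicated
masking step that strips the bright cell-free "V-shape" wedge from
rectangular tips.  Everything is platform-independent: the geometry,
material and optics live in a single `PlatformConfig`.

A synthetic scene renderer (`pillartrack.synth`) produces realistic
recordings — noise, shadows, bubbles, illumination gradients, the
V-wedge — together with *exact* ground truth (per-frame centroids, gap
and tissue masks), so the entire pipeline is testable and benchmarked
without laboratory data.

## Worked example

`python examples/01_render_and_track.py` renders the circular-pillar
benchmark scene (370×134 px, 100 fps, 2 Hz sinusoidal gap modulation
of 12 px amplitude, realistic artifacts), tracks it, and scores the
result against the generator's ground truth:

```
rendered 120 frames of (134, 370) px at 100.0 fps
platform: circle tips, k = 0.445 uN/um
diastolic gap: 474.8 um, peak deflection: 29.95 um
area error 0.23% (accuracy 99.77%), displacement error 0.25%, centroid error 0.048 px
```

Reading: with k = 0.445 µN/µm the ~30 µm peak gap deflection
corresponds to ~6.6 µN of peak contraction force; the segmentation
recovers the tissue area within a fraction of a percent and the
tracked gap amplitude is within 0.25% of the programmed motion, with
sub-0.05 px centroid accuracy.

`examples/02_force_and_kinetics.py` continues to forces and per-cycle
metrics; `examples/03_batch_folder.py` shows the batch workflow, which
is also available from the shell:

```
pillartrack track <video_dir> --config run.yaml --out results/
pillartrack synth --scene rect-std --out bench/
pillartrack evaluate results/video_detail.csv bench/rect-std_truth/truth.csv
```

Per video the batch writes a per-frame detail table (distance,
deflection, force, area), a per-cycle metrics table and a detection
snapshot PNG; per batch a summary table (one row per video, mean ±
SEM over cycles), the selected time-series graphs, and a plain-text
log.  Failures are isolated per video, results are independent of the
worker count, and manual Otsu/morphology overrides are recorded as
provenance columns.

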