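# Methods

`pillartrack` measures the contractile force of engineered heart
tissues (EHTs) suspended between two elastic pillars, from brightfield
video alone.  This note documents the models, the numerical choices,
the synthetic benchmark that validates them, and the limits of what
that validation shows.

## Measurement principle

A beating EHT bends its two anchoring pillars toward each other.  For
the small deflections involved, each pillar behaves as a linear spring:
measuring the change of the inter-pillar tip distance δ (µm) and
knowing the effective stiffness k (µN/µm) gives the force of
contraction F = k · δ_per-pillar directly.  The whole pipeline is
therefore an exercise in measuring δ accurately and converting it with
a defensible k.

## Segmentation and tracking

Transparent elastomer (typically PDMS) pillar tips image *bright* in
brightfield; the compacted, opaque tissue around them images *dark*.
Per frame:

1. **Pre-processing** — grayscale conversion (BT.601 luma), bilateral
   smoothing (window 9 px, σ_color 50 intensity levels, σ_space 25 px;
   edge-preserving so the tip boundary stays sharp), then a
   morphological opening (n erosions followed by n dilations, 3×3
   square element, default n = 1).  n above 2 distorts tip shapes and
   triggers a warning.  Deeper-than-8-bit sources are rescaled to
   8 bits at load so one 256-bin histogram convention applies
   everywhere.
2. **Thresholding** — Otsu's criterion (between-class variance
   maximization over the 256-bin histogram, smallest maximizing
   threshold on ties).  A constant frame has no threshold and is
   flagged for manual override.  A user-supplied threshold bypasses
   Otsu entirely and is recorded in the outputs.
3. **Per-half detection** — the frame is split at ⌊W/2⌋ into two
   halves, one pillar each.  In each half, connected bright components
   are sorted by area and the one closest to the expected tip area
   (platform geometry / (µm/px)²) is the pillar, admissible within a
   ×3 / ÷3 band.  The centroid is the raw image-moment centroid of the
   binary component — naturally subpixel, since anti-aliased edge
   pixels flip membership as the tip moves.
4. **V-shape masking** (rectangular tips only) — the bright cell-free
   wedge that fuses to a rectangular tip's inner face is removed by
   exhaustively sliding a rectangle of the expected tip size (integer
   translations) over the component and keeping the placement with
   maximum overlap; component pixels outside it are cleared.  Best
   overlap below half the expected tip area fails the frame.
5. **Tissue area** — the largest dark connected component, minus any
   pixels it shares with the fitted pillar shapes (the same
   pillar-exclusion convention a manual reference measurement uses).

Inter-centroid Euclidean distance per frame, converted by µm/px, is
the raw contraction signal.  Each pillar is detected independently per
frame — no template matching or optical flow — so the method has no
drift accumulation and no requirement that the tissue sit centered.

Frames where detection fails are linearly interpolated from their
neighbors, capped at 3 consecutive frames and 5% of the recording;
beyond either cap the recording is rejected as unreliable rather than
silently patched.

**Baseline.** The diastolic reference distance is the median of the
upper decile of the distance series.  An order statistic was chosen
over "first frame" or "global maximum" because recordings may start
mid-beat and noise makes a single extreme frame a poor reference; the
decile (rather than a wider quantile band) keeps the reference within
a fraction of a µm of true diastole even for sinusoid-like waveforms
that spend little time fully relaxed, so deflection never goes
meaningfully negative.
Deflection is baseline minus distance, so the force trace is
baseline-zeroed by construction.

## Force conversion

Euler–Bernoulli cantilever, point load at the tissue-attachment height
`a`, deflection observed at the tip:

    δ_tip = F a² (3L − a) / (6 E I)   ⇒   k = 6 E I / (a² (3L − a))

with I = πD⁴/64 (circular cross-section) or I = w·b³/12 (rectangular,
thickness `b` along the pull direction).  `a = L` recovers the
textbook 3EI/L³.  For top-view platforms that observe the attachment
height itself, a config switch (`deflection_read_at="attachment"`)
uses k = 3EI/a³ instead; the default is the tip readout.

With E in Pa and lengths in µm, E·I/length³ is 10⁻⁶ µN/µm, hence the
single hard-coded conversion factor.  The measured gap change is
attributed symmetrically, half to each pillar: F = k · δ/2.  When
comparing absolute forces against other implementations, note that an
implementation attributing the full gap change to one pillar will
report twice the force.

**Resting tension** (preload) = k · (design gap − baseline
distance)/2, floored at zero with a warning if the baseline exceeds
the design gap.  It is reported separately, never re-subtracted from
the already baseline-zeroed force trace.

**Force per area** divides each frame's force by the same frame's
segmented tissue area (µN/µm²); frames without a valid area are NaN
and excluded from cycle statistics.

## Kinetics

The beating frequency is the largest non-DC peak of the amplitude
spectrum in 0.2–8 Hz (parabolically interpolated between bins).  If no
peak rises 3× above the in-band spectral median the trace is declared
aperiodic and filtering falls back to a 10 Hz cutoff.  The low-pass is
a 4th-order Butterworth applied forward-backward (zero phase — timing
metrics would otherwise be shifted by the filter delay), cutoff
min(10·f₀, 0.8·Nyquist): ten harmonics preserve the waveform shape
that T10/T90 depend on.

Cycles are peaks (prominence ≥ 20% of the trace span) bounded by the
local minima on either side; a bounding "minimum" that falls on the
first or last sample means the recording cut into that cycle, and the
cycle is discarded.  Per cycle, amplitude is peak minus start value;
10%/90% crossing times are linearly interpolated between samples
(upstroke times from the cycle start, decay times from the peak);
contraction/relaxation velocities are the extreme central-difference
slopes within each limb.  Per-recording tables report mean ± SEM over
cycles.

## Synthetic benchmark

`pillartrack.synth` renders the scene the detector assumes: bright
background, dark tissue ellipse, two bright tips whose programmed
centroids follow a contraction waveform symmetrically about the frame
center.  Rendering is supersampled 4× with block averaging, so shape
boundaries carry true area-coverage anti-aliasing and subpixel motion
is representable; the analytic centroid of a rendered tip agrees with
the programmed one within 0.25 px.  The tissue ellipse scales with the
gap, so its area pulses with each beat, and the exact per-frame tissue
mask (tissue minus tips, wedge and bubbles) is emitted as ground
truth.  Artifacts: pillar shadows (intensity drop crescents), static
air bubbles, a linear illumination gradient, Gaussian sensor noise,
and the V-wedge for rectangular tips.

Two fixed fixture scenes emulate the two common platform families at
desk scale — frames of 370×134 px (half the recommended minimum
recording size of 738×266), 1.2 s at 100 fps, 2.5 µm/px:

* `circular-std`: 16 px-radius round tips (80 µm at 2.5 µm/px),
  sinusoidal gap modulation, amplitude 12 px at 2 Hz, noise σ 4,
  shadows, 4 bubbles, 6% illumination tilt.
* `rect-std`: 36×22 px rectangular tips, pulse-train modulation,
  amplitude 10 px at 2 Hz, a 300 px² V-wedge on each tip, noise σ 7
  (the rectangular-platform family shows distinctly noisier
  backgrounds in practice), shadows, 5 bubbles, 8% tilt.

The benchmark protocol re-renders each scene with several seeds (fresh
noise and artifact draws), runs the full pipeline, and reports the
first-frame tissue-area error and the peak-to-trough displacement
amplitude error against ground truth, the amplitude estimated as the
2nd–98th percentile span of the gap series for tracked and true series
alike.  Frequency recovery uses 10 s waveforms at 100 fps (2 Hz
paced-like pulse train, 1.2 Hz spontaneous-like asymmetric beat).

**What this does and does not show.**  The generator reproduces the
contrast structure, artifact types and motion scales of real
recordings, so passing it demonstrates the pipeline's geometry,
numerics and robustness logic.  It does not capture optics
(point-spread blur, defocus), non-elliptical tissue outlines,
tissue-intensity texture, or drifting illumination; accuracy on real
videos must still be spot-checked via the detection snapshots the
batch runner writes for every video.

## Known limitations and edge cases

* Small-deflection linear beam theory only; no substrate compliance,
  no per-pillar stiffness asymmetry.
* Exactly two pillars, circular or rectangular tips.  The final
  shape-approximation step is isolated, so other tip geometries only
  require a new approximation function.
* Compressed AVI codecs are not decoded (uncompressed/DIB only);
  proprietary .nd2 is rejected explicitly.
* The V-wedge masking searches integer translations only; its
  placement quantization is the dominant displacement-error term on
  rectangular platforms (about 10% of a 10 px amplitude on the
  benchmark, versus well under 1% for circular tips).
* Recordings shorter than 2 s cannot provide a spectral frequency
  estimate, and kinetics are skipped for them.
* Frame rates below 70 fps trigger a warning: contraction upstrokes
  become undersampled and T10/T90 unreliable.
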