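# Methods

This note documents the models and procedures implemented in
`fundus_eval`, the parameter choices that matter, and what the synthetic
studies do and do not demonstrate.

## The measurement chain

### Vessel amount

The vessel amount of an image is the number of set pixels in its binary
vessel-segmentation map.  The package takes the map as input (any
segmenter can produce it); masks must be strictly binary ({0,1} or
{0,255}).  `ridge_segment` provides a classical multiscale Frangi
vesselness filter with Otsu thresholding as optional plumbing for
pipelines without an external mask — it is a rough classical baseline
(Dice ≈ 0.6–0.9 against ground truth on low-noise phantoms), not a tuned
segmentation method.

### Zone-B SNR

Zone B is the annulus between 2·D and 3·D from the optic-disc centre,
with D the disc diameter; distances are Euclidean on pixel centres and
both boundaries are inclusive.  Per image:

1. **Skeletonize** the mask (morphological thinning) and cut the skeleton
   at branch points (skeleton pixels with more than two 8-connected
   skeleton neighbours).  Each remaining arc is a *segment* with an
   ordered pixel path.
2. **Restrict** each segment to zone B; maximal in-zone runs shorter than
   `min_seg_len` (default 10 px) are skipped, since "n points at even
   distances" needs a usable arc.
3. **Sample** `n_points` (default 5) per run at arc-length fractions
   (i + ½)/n — never on endpoints or branch points, where the tangent is
   ill-defined.
4. **Local frame**: the tangent is the total-least-squares line direction
   of a ±3-pixel window of the path; the normal is the tangent rotated
   90°.  On straight digital segments the tangent is accurate to well
   under 5° at any orientation.
5. **Half-width**: from the sample position, march along ±normal in
   0.25-px steps until the first off-mask pixel; the half-width is the
   mean of the two one-sided distances.  The wall is defined by the
   *mask*, not by image intensity, because the measurement is specified
   on the segmented vessel map.
6. **Profile**: read intensities at unit offsets k along the normal.
   Signal = mean over within-vessel positions (|k| ≤ half-width and on
   the mask).  Noise = sample standard deviation (ddof = 1) of the
   background values at offsets half-width < |k| ≤ half-width + 5, both
   sides pooled (10 values); a per-side variant is available
   (`noise_mode="one_sided"`).
7. **Per-point SNR** = signal / noise; the per-image value is the
   arithmetic mean over retained points.

Records are *dropped and counted, never imputed* when the band leaves the
frame, when any band pixel lies on a vessel (a neighbouring vessel would
corrupt the noise estimate — the noise is defined outside the vessel
wall), when rounding collisions leave fewer than `noise_band − 1` usable
pixels per side, or when the band is constant (degenerate noise).

Two numerical choices deserve emphasis:

* **Nearest-pixel profile reading (default).**  Bilinear interpolation at
  subpixel positions averages up to four pixels and attenuates the noise
  standard deviation by ≈ √(4/9) ≈ 2/3 on average, which would inflate
  SNR by roughly 50 %.  Profiles are therefore read from the nearest
  actual pixels (the noise definition speaks of neighbouring *pixels*);
  `interp="bilinear"` is available for smooth-profile work but is not the
  calibrated path.
* **Finite-sample debiasing (default).**  With m = 10 noise values, the
  plug-in ratio signal/s overestimates signal/σ by
  E[σ/s] − 1 = √((m−1)/2)·Γ((m−2)/2)/Γ((m−1)/2) − 1 ≈ 9.4 %.  The
  denominator is multiplied by this exact Gaussian-theory factor
  (`debias=True`), making the per-point SNR unbiased for (b − c)/σ on the
  phantom model.  The `noise` field of an `SNRRecord` is the corrected
  scale estimate, so `snr = signal/noise` holds exactly.

### Cohort statistics

Unpaired two-sided t-test, pooled-variance Student's form by default
(Welch via flag), through `scipy.stats.ttest_ind`.  Cohen's d uses the
pooled standard deviation; with equal n it reduces to
diff/√((s₁²+s₂²)/2).  The mean difference is also reported as a
percentage of the image size — the total pixel count of the standardized
frame (1024² = 1,048,576 by convention) — and of the grand mean of the
two cohorts.  No multiple-testing correction is applied across the two
metrics.  Significance level α = 0.05.

### Turing-test analysis

Per reader: sensitivity (real called real), specificity (synthesized
called synthesized), accuracy, mean examination time.  Accuracy equals
the response-count-weighted mixture of sensitivity and specificity
exactly; a reader missing one truth class keeps a NaN for the undefined
rate and is excluded pairwise.  Readers are grouped by specialty or by
specialty × 5-year experience.

Group contrasts use a **reader-level cluster bootstrap**: readers are
resampled with replacement within each group and the group estimate (mean
of per-reader rates) is recomputed; percentile CIs; the p-value against
the reference group is the two-sided bootstrap sign probability of the
group difference, with a (1+count)/(B+1) correction.  This preserves
exactly the clustering structure that a population-average (GEE-type)
analysis of such data assumes, and simulation shows it is calibrated
(type-I error ≈ 0.05–0.06 at 12 readers per group).  A two-stage variant
(`second_stage=True`) additionally resamples each sampled reader's
responses; it is deliberately conservative — within-reader sampling
variation is then counted twice — and is provided for sensitivity
analyses only.  Elapsed-time contrasts use the same machinery on
reader-mean times.

## The synthetic phantom

`generate_fundus` renders, in order: background level *b* inside the
retina circle; a Gaussian macular darkening; a bright disc plateau; the
vessel tree at constant intensity *b − c* (top-hat cross-section); then
optional Gaussian edge blur and additive N(0, σ²) pixel noise, clipped to
[0, 1].  Because vessels are painted last, every vessel pixel is exactly
*b − c* before noise, so the per-point SNR has the analytic value
(b − c)/σ when `edge_blur = 0` and σ > 0 (reported as `expected_snr`;
NaN when σ = 0).

The vessel tree grows by a recursive random walk: roots on the disc rim
fanning toward the retina centre, per-step Gaussian heading jitter
(`tortuosity`), branching with a fixed per-step probability into two
children whose half-widths taper multiplicatively (`width_taper`), and
termination at the retinal margin or at sub-pixel width.  There are no
anastomoses by construction; crossings of independently grown branches
can occur, as they do in projected 2-D fundus images.

Defaults (chosen once, as a realistic operating point):

| parameter | default | rationale |
|---|---|---|
| b, c, σ | 0.60, 0.26, 0.20 | analytic SNR (b−c)/σ = 1.70, the regime reported for real fundus cohorts |
| retina radius | 0.47 × frame | retina fills the frame with a small dark margin |
| disc diameter | 0.117 × frame, at 0.71 of the width | disc ≈ 1/8 of the retinal diameter, temporally placed |
| initial half-width | 4 px | main arcade calibre ~8–10 px at 1024 |
| branch probability | 0.015/step | yields ≈ 11 % vessel-pixel fraction at 1024², matching segmented real images |
| reader/image effect sd | 0.9 / 0.5 logits | reproduces the between-reader spread (≈ 12–20 %-points) seen in reader studies |

The additive-Gaussian SNR oracle is exact only while clipping at [0, 1]
is negligible; intensity settings should keep vessel intensity ≥ ~1.7 σ
above 0 and background ≥ ~2 σ below 1 (at the defaults the residual
clipping bias is ≈ +2–4 % and the recovery band of 10 % absorbs it).

The reader simulator draws each answer Bernoulli-correct with
logit p = a + u_reader + σ_img·z_image, u ~ N(0, σ_reader²), z shared
across readers.  The intercept *a* is calibrated by Gauss–Hermite
quadrature so that the *marginal* correct rate equals the requested
latent sensitivity/specificity — the population-average quantities a
GEE-style analysis estimates — rather than the conditional (median-reader)
rate, which would be shrunk toward ½ by the random effects.  Elapsed
times are log-normal with the profile's mean and sd.

### What the phantom does not emulate

Uneven illumination, colour (images are single-plane; for RGB input the
green channel is used, the fundus-imaging standard), central light
reflexes on vessels, calibre variation along a branch, pathology (ERM,
DR, AMD), camera vignetting, and JPEG artefacts.  Passing the synthetic
studies therefore shows the *measurement chain* is correct and calibrated
on a known model; it does not certify performance on clinical images,
where segmentation quality dominates.

## Preprocessing

Retina detection: Gaussian smoothing (σ = 2 px), Otsu threshold, binary
opening, largest 8-connected component, bounding circle.  Centering:
square crop around the detected centre with a 5 % margin, bilinear resize
to the target frame (1024 px convention; masks would use nearest-
neighbour), zero padding outside the original frame.  Inputs already
standardized are returned unchanged, making the operation exactly
idempotent.  Quality rules are deliberately simple, tunable proxies for
clinical exclusions: mean brightness < 0.08 → "dark", fraction of pixels
≥ 0.98 above 0.25 → "saturated", retina radius above 0.97 of the half
frame width → "zoomed" (peripheries cut off).  The exact clinical
thresholds behind such exclusions are not standardized; these defaults
are placeholders to be tuned per camera.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the simulation studies at
desk scale — 224–512-px frames with geometry scaled proportionally,
20-image cells for SNR recovery, 200-image cohorts for null comparisons,
40 × 100 reader studies — sizes at which the Monte-Carlo error is well
inside each tolerance.  All randomness flows from one master seed through
`numpy.random.SeedSequence` substreams keyed by cohort and image index,
so outputs are bit-reproducible and independent of generation order;
rerunning a pipeline config reproduces every CSV and PNG byte-for-byte.

## Known limitations

* Vessel walls are located from the binary mask; a systematically dilated
  or eroded mask biases both half-width and signal.
* Per-point SNR assumes locally straight vessels across the profile span;
  strongly curved segments shorter than the tangent window are skipped
  rather than modelled.
* The skeleton of crossing vessels fragments into many short segments;
  points whose noise band touches another vessel are dropped, which in
  very dense plexuses can leave few retained points per image (the count
  is reported as `n_points`).
* The cluster bootstrap needs a handful of readers per group for stable
  CIs; single-reader groups are flagged as degenerate.
* The Frangi-based segmenter is a baseline, not a competitor to learned
  segmentation.
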