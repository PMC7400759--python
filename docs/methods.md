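# Methods

`fundusavr` measures the retinal arteriole-to-venule diameter ratio
(A/V-ratio) from monochrome fundus video and provides the statistical layer
that relates the ratio to intracranial pressure (ICP).  This note documents
the models, the numerical choices, and what the synthetic fixtures do and do
not establish.

## The measurement chain

**Screening.**  Video is split into frames (16 fps by default).  Each frame
is classified fundus / non-fundus on a 192 × 192 px reduction using three
deterministic features: the contrast between a bright circular field of view
and its dark surround, a mid-range mean-intensity term, and dark-ridge
(vessel) texture energy from a Sato vesselness filter.  The FOV term gates
the other two multiplicatively, because texture without the circular field
of view is not evidence of a fundus.  The decision threshold (0.5) and
feature scales were frozen once against a seeded 200-fixture calibration set
(100 degraded phantoms, 100 non-fundus frames; regenerable with
`scripts/calibrate_is_fundus.py`, which reports 100 % accuracy on that set).
A learned classifier would be the natural alternative; a deterministic
feature screen was chosen so results carry no opaque weights.

**Quality score.**  Each fundus frame receives a 0–100 score: the weighted
mean (equal weights ¼ by default) of optic-disc detection confidence, vessel
clarity (95th percentile of Sato vesselness), sharpness (99th percentile of
the Sobel gradient), and brightness (1 − |mean − 0.45| / 0.25, i.e. a target
mid-level 0.45 with a full-width tolerance of 0.5).  The texture metrics use
upper percentiles of a lightly denoised frame (Gaussian σ = 1 px): mean
gradient energy would reward pixel noise rather than structure.  Frames
below `q_min` (default 50) are dropped; the frame with the highest score is
the registration reference, Max(Q).

**Disc localization.**  The smoothed frame is grey-closed (9 × 9) to
suppress vessels crossing the disc, thresholded halfway between the FOV
background (median) and the peak (99.9th percentile), and the largest
compact blob is summarized by centroid and area-equivalent radius.
Confidence combines contrast and blob solidity.  The "disc radius" used for
the two-disc-radii sampling locus is the circle-equivalent (geometric-mean)
radius; seeds outside 1.8–2.2 radii are warned about, outside 1.5–2.5 they
would simply be unusual, not rejected.

**Registration.**  Each usable frame is mapped onto the reference by a rigid
pose (x, y, α), rotation counterclockwise about the frame centre, α
normalized to (−180°, 180°].  Estimation is two-stage: a coarse,
translation-invariant rotation from the angular cross-correlation of
windowed, band-passed Fourier magnitudes in polar coordinates (the 180°
ambiguity is resolved by trying both candidates), then Nelder–Mead
refinement of the masked normalized cross-correlation over all three
parameters.  Both rotation *and* translation are corrected; correcting only
rotation would leave seed positions misaligned under camera shake.  Frames
whose best similarity stays below 0.6 are dropped with a logged reason.  On
noiseless phantoms the grid test recovers rotation to ≪ 0.5° and translation
to ≪ 1 px over α ∈ [−15°, 15°].  Warping for measurement uses bicubic
interpolation (bilinear adds measurable extra smoothing to narrow vessels);
pixels leaving the frame become NaN and are excluded from all profile fits.

**Diameter measurement.**  From each seed the tracer walks the locally
darkest ridge 25 steps (2 px each) in both directions, recentering on the
subpixel minimum of the perpendicular profile of a σ = 1 px smoothed copy at
every step, and stopping at the FOV boundary, on invalid pixels, at
implausible turns (> 50°), or when the trough depth falls below 0.03.  At
each of the up-to-51 locations the perpendicular profile (half-width 12 px,
1 px spacing, bilinear samples of the *unsmoothed* frame) is fitted with

    I(t) = offset − amplitude · exp(−(t − μ)² / (2σ²))

by bounded least squares (`scipy.optimize.curve_fit`; initial values: μ at
the profile minimum, σ from the trough's second moment, offset from the
profile ends; bounds σ ∈ [0.5, 12] px, μ within the central half).  The
diameter is the full width at half maximum, 2√(2 ln 2) σ ≈ 2.3548 σ — an
edge-to-edge width at another level would differ only by a fixed factor and
cancel in the ratio, but FWHM is the convention adopted and tested.  Points
are rejected when the profile leaves valid pixels, the fitted amplitude is
below 0.05, or the residual RMSE exceeds max(0.015, 0.2 · amplitude); the
RMSE gate is what removes profiles contaminated by vessel crossings, playing
the role a learned patch validator would otherwise play.  A vessel
measurement needs at least 13 accepted points (≥ 25 % of 51) or it is
rejected with per-reason counts; the per-vessel summary is the **median**
accepted FWHM, robust to residual contamination.

**Classification and A/V aggregation.**  In a measured pair the venule is
the vessel ranking darker-and-wider (rank sum of median fitted amplitude and
summary diameter; ties go to the darker vessel).  Consistent user-supplied
seed labels override the ranking with a logged notice.  Per frame, the ratio
is arteriole summary / venule summary (< 1 when the arteriole is narrower);
per full second (16 frames at default fps) the reported A/V is the median of
the per-frame ratios, with the number of contributing frames recorded.
Seconds with no usable frame are omitted, never imputed.  Diameters stay in
pixels throughout: the ratio is dimensionless, so pixel-to-mm calibration
cancels and none is attempted.  Seeds are marked once on the reference frame
and reused on every registered frame rather than re-picked per frame.

## The statistical layer

Observations are rows (patient, epoch, mean ICP in mmHg, median A/V).
Because epochs repeat within patients, every regression is a linear
mixed-effects model with a patient random intercept, fitted by REML
(statsmodels `MixedLM`) with Wald 95 % intervals.  Numerical details: the
optimizer chain is L-BFGS → BFGS → Powell → Nelder–Mead, accepting the first
fit that both converges and passes a sanity check (marginal predictions
within 10 data standard deviations — optimizers occasionally report
convergence at a degenerate point); boundary fits with zero random-intercept
variance are legitimate and retained.  For exactly identical groups the
group-difference p-value is defined as 1 rather than the 0/0 NaN.

* **Regime fits**: `median_av ~ mean_icp` separately on ICP < 15 mmHg and
  ≥ 15 mmHg.
* **Slope comparison**: one joint model with centred ICP, a ≥ 15 indicator,
  and their interaction; the Wald p of the interaction term tests slope
  equality.
* **Group means at 20 mmHg**: within the ≥ 15 regime, a binary ≥ 20
  indicator model; marginal stratum means with Wald intervals.
* **ROC**: the empirical curve with *strict* positivity, test-positive iff
  median A/V < threshold (matching the clinical "< 0.8015" cut-off; ties at
  a threshold count as negative).  The trapezoidal AUC then equals the
  Wilcoxon–Mann–Whitney statistic with ties counted half, which is asserted
  against brute-force pair counting in the tests.  The AUC interval is a
  seeded, class-stratified bootstrap (2,000 resamples) — simpler to verify
  by simulation than an asymptotic formula; the seed is recorded in the
  output.
* **Sensitivity/specificity at the cut-off**: exact Clopper–Pearson 95 %
  intervals at the observation level (the intervals are *not*
  patient-clustered; with repeated epochs per patient they are anti-
  conservative, and are labelled observation-level for that reason).
  LR+ = sensitivity / (1 − specificity).  Note that with sensitivity 0.94
  and specificity 0.50 this formula gives 1.88, not 9.0; the package always
  reports the formula-consistent value.

## Synthetic fixtures

**Frame phantoms** render what the screen and measurement stages assume: a
bright circular FOV (level 0.55) on a dark surround (0.02), a quasi-
elliptical disc plateau whose sigmoid edge has its half-maximum exactly on
the ellipse (so a half-contrast threshold recovers the true boundary), and
vessels as inverted Gaussian ridges — the intensity deficit at distance *d*
from the centerline is contrast · exp(−d²/2σ²), making the generator the
definitional oracle for the Gaussian profile estimator.  Corruptions are
applied render → blur → noise → rigid transform, so recorded poses refer to
the emitted image; rotation is about the frame centre with bilinear
interpolation and outside-FOV fill.  The default raster is 640 × 512, half
the camera's native 1280 × 1024, to keep test runtimes reasonable; native
size is a spec option.  The default paired phantom has a 7 px arteriole
(contrast 0.20) and a 10 px venule (contrast 0.30) leaving the disc as
gentle arcs whose second control points sit exactly at two disc radii — the
canonical seed positions.  Default degradation (noise sd 0.01, blur
σ = 0.6 px, jitter 1° / 1 px per frame) is mild; note the blur inflates a
7 px FWHM to ≈ 7.14 px and a 10 px one to ≈ 10.10 px, so measured ratios on
the default video run ≈ 0.710–0.715 rather than exactly 0.700 — a property
of the rendered scene, not an estimator bias (the noiseless, blur-free
oracle recovers widths to < 0.11 px).

Videos interleave exactly round(n · fraction) non-fundus frames at seeded
positions — the fraction is honoured exactly rather than in Bernoulli
expectation so frame-count contracts are deterministic.  All generators are
pure functions of (spec, seed); the truth manifest (poses, disc geometry,
vessel widths, fundus flags, seed) round-trips losslessly through JSON.

**Cohorts** mirror the statistical model: per-patient Gaussian random
intercepts (sd 0.05), residual sd 0.02, and a piecewise-linear population
mean hinged at 15 mmHg with slopes +0.0017 / −0.0023 A/V per mmHg — the
published regime estimates used as generating truths.  The anchor value at
the hinge (0.88) is back-computed from the published ≤ 19 mmHg stratum mean.
Observation counts per patient are Poisson around the design mean (the
14-patient, 6.1-obs default yields ≈ 86 rows).  Generated ratios are
clipped to (0, 2) and clip events counted — defaults never clip.  A second
generator produces the two-stratum design (means 0.8757 / 0.8551 across the
20 mmHg boundary) used for group-mean recovery.

**What passing does not show.**  Phantoms contain no pathology, no uneven
illumination, no lens distortion, no vessel pulsation, and exactly Gaussian
cross-sections; real vessels have flatter (more top-hat-like) profiles, for
which the Gaussian FWHM is only an approximation (the top-hat test bounds
that model error at ~15 % for a 9 px band — and it largely cancels in the
ratio).  Cohort recovery shows the statistical layer is consistent for its
own generating model, not that the published clinical estimates are
reproducible — the original recordings are not available.

## Simulation sizes

Parameter-recovery runs use 200 replicates (slope and group-mean targets)
and 1,000 replicates for CI coverage; the registration grid uses 25 pose
combinations and the end-to-end video check 3 s at 16 fps.  These sizes put
Monte-Carlo error well inside the asserted tolerances (e.g. the SE of the
200-replicate mean slope is ≈ 8 × 10⁻⁵ against a ± 3 × 10⁻⁴ band).

## Known limitations

* Registration assumes a rigid in-plane pose; out-of-plane tilt and lens
  distortion are out of scope.
* The fundus screen is calibrated on phantoms; on real video its threshold
  is configuration, not a validated operating point.
* Whole-image vessel segmentation, CRAE/CRVE summary formulas and venous
  pulsation analysis are out of scope.
* Mixed-model inference is Wald/REML with a random intercept only; no
  random slopes, no temporal correlation within the infusion.
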