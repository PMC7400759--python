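# fundusavr

Retinal arteriole/venule-ratio (A/V-ratio) measurement from monochrome
fundus video, with the statistical layer relating the ratio to intracranial
pressure (ICP).

Raised ICP distends the compliant retinal venules more than the arterioles,
so the dimensionless ratio of paired vessel diameters, measured at a fixed
locus two optic-disc radii from the disc centre, falls as ICP rises above
~15 mmHg.  This package implements the full desk-side pipeline for that
measurement — for image-analysis researchers and for anyone evaluating
non-invasive ICP surrogates:

1. **Screening** — split video into frames, reject non-fundus frames with a
   deterministic classifier on a 192 × 192 reduction, score each frame
   0–100 (disc, vessel clarity, sharpness, brightness), pick the best frame
   Max(Q) as reference.
2. **Geometry** — localize the optic disc; estimate each frame's rigid pose
   (x, y, α) relative to Max(Q) and resample it onto the reference.
3. **Measurement** — from one manually marked seed per vessel, trace the
   centerline 25 points in each direction and fit a Gaussian trough
   `offset − A·exp(−(t−μ)²/2σ²)` to each perpendicular intensity profile;
   the diameter is the full width at half maximum, FWHM = 2√(2 ln 2)·σ.
   Per second of video (16 frames), A/V = median over frames of
   (arteriole FWHM / venule FWHM).
4. **Statistics** — linear mixed-effects regressions of median A/V on mean
   ICP with patient random intercepts (REML), fitted separately below and
   at/above the 15 mmHg split, a slope-difference (interaction) test, a
   group-mean comparison at the 20 mmHg pathology boundary, and ROC /
   sensitivity–specificity analysis at the 0.8015 cut-off (lower A/V =
   test positive).

No clinical recordings ship with the package.  A first-class synthetic
module generates ground-truthed fundus phantoms (vessels rendered as
inverted Gaussian ridges of known FWHM, known disc geometry and known
per-frame pose) and synthetic ICP/A-V cohorts with known random-intercept
structure, so every stage is tested against generating truth.
See `docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate a 3-second phantom video (true widths: arteriole 7 px, venule
10 px), measure it, then analyze a synthetic cohort:

```
$ fundusavr simulate video --out demo/vid --n-seconds 3 --seed 7
wrote 48 frames + manifest + seeds to demo/vid

$ fundusavr measure --frames demo/vid --seeds demo/vid/seeds.json --out demo/run
3 per-second A/V records -> demo/run

$ cat demo/run/av_records.csv
second_index,arteriole_px,venule_px,av_ratio,n_frames_used
0,7.252891465639354,10.220390648230582,0.7115662581899591,16
1,7.301007624856542,10.18082857366564,0.7165917481745812,16
2,7.269921196281132,10.209398122104108,0.7118907712398633,16
```

Every second used all 16 frames; the measured ratio sits near the
generating 7/10 = 0.70 (the default blur widens the 7 px arteriole slightly
more in relative terms — see the methods note).  The run directory also
contains the per-frame screening report, disc report, pose table and
per-point measurement counts, so every dropped frame is accounted for.

```
$ fundusavr simulate cohort --out demo/cohort.csv --seed 1
wrote 77 observations to demo/cohort.csv

$ fundusavr analyze --table demo/cohort.csv --out demo/analysis.json --seed 5
analysis -> demo/analysis.json

$ python -c "import json; a=json.load(open('demo/analysis.json')); \
  print(round(a['mixed_model_high']['slope'],5), \
        round(a['slope_comparison']['p_interaction'],4), \
        round(a['roc']['auc'],3))"
-0.00385 0.0007 0.585
```

The fitted high-regime slope (−0.0039 A/V per mmHg in this draw) estimates
the cohort's generating value of −0.0023 within sampling error, the
interaction p-value detects the slope change at 15 mmHg, and the AUC
quantifies how well a low A/V flags ICP ≥ 20 mmHg in this draw.

The same steps are available from Python (`fundusavr.measure_video`,
`fundusavr.analyze_table`, `fundusavr.generate_video`,
`fundusavr.generate_cohort`, ...).

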