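# Methods

## The biomarker model

The quantity of interest is SUV_X%, the X-th percentile of the
standardised-uptake-value distribution over all voxels of an organ mask.
SUV is computed as activity concentration (Bq/mL, decay-corrected at
reconstruction time — the package never re-corrects) × body weight (g) /
injected dose (Bq), giving g/mL. Percentile-of-histogram metrics are used
instead of SUV_max because a handful of mislabelled voxels at an organ
boundary can dominate a maximum but barely move a percentile.

Percentiles follow the linear-interpolation-between-closest-ranks
convention: for n sorted values, the fractional rank of percentile X is
r = 1 + (n − 1)·X/100, interpolated between floor(r) and ceil(r). This is
the single most consequential numerical convention in the package (organ
histograms are heavy-tailed, so conventions disagree visibly in the upper
tail); it is therefore explicit in `organ_percentiles` and configurable via
the `method` argument. The default search grid is {5, 10, …, 95, 100}.

Per patient and organ, the predictor is the **maximum SUV_X% over
on-treatment scans** (scan_day ≥ 0). Baseline scans never enter the
predictor; they feed the normative range instead. Scans acquired after the
clinical diagnosis date are kept by default and can be excluded with
`censor_post_diagnosis=True`.

The optimal percentile is SUV_OPT% = argmax_X AUROC(X). AUROC is computed
through the Mann–Whitney identity U/(n₁n₂) with average ranks, i.e. ties
credited ½. Ties in the argmax resolve to the *smallest* percentile, on
the rationale that lower percentiles are less sensitive to segmentation
error. Classification polarity is fixed: score > threshold ⇒ irAE-positive.
The operating point maximises Youden's J = sensitivity + specificity − 1;
J-ties resolve to higher specificity, then lower threshold, so the
degenerate all-scores-equal curve returns the observed score with
specificity 1.

Group comparisons use a two-sided Wilcoxon rank-sum test: exact enumeration
of all C(n, n₁) label assignments when the combined sample is ≤ 12 and
tie-free, otherwise a normal approximation with tie and continuity
corrections. The exact branch counts assignments with |U − μ_U| at least as
large as observed, which matches the conventional two-sided exact p.

The normative range for each organ is CI95 = [μ − 1.96σ, μ + 1.96σ], with
μ, σ the sample mean and (n−1)-denominator SD of baseline SUV_OPT% across
patients who experienced **no irAE of any organ** (not merely none of the
target organ). Longitudinal flagging uses only the upper limit — the
pathology of interest only raises uptake — with a strict inequality, so a
value exactly at the limit is not a flag. Lead time = clinical day − first
flag day (positive when imaging leads). The cohort-level monitoring report
is deliberately descriptive: scan schedules are irregular, so no
inferential comparison of detection timing is attempted.

For organs whose cohort contains a single class (e.g. a zero-event
simulation), percentile selection is skipped with a recorded notice and the
normative range is built at a fallback percentile (default 95).

## Segmentation quality

Masks are treated as inputs (in practice produced by a CNN segmentor, which
is out of scope here); their quality is assessed with the Dice coefficient
2|A∩B|/(|A|+|B|) and the average symmetric surface distance (mean of the
two directed mean nearest-surface distances). Surfaces are 6-connected
boundary voxels, with the array edge counting as background, and distances
are Euclidean in world millimetres. Both metrics attain their ideal values
simultaneously iff the masks coincide.

## The synthetic cohort generator

The generator exists because the clinical images behind the published
analysis are not deposited. It aims to reproduce the *statistical*
structure the analysis exploits, not anatomy:

* **Phantom.** Thyroid = two small ellipsoidal lobes (9×9×18 mm semi-axes)
  joined by a 5-mm isthmus; lungs = two 34×40×55 mm ellipsoids; bowel = a
  14-mm-radius tube along a serpentine path. Geometry is specified in
  world mm on a default 64×64×96 grid at 4 mm (≈ 4.8k bowel, 9.8k lung,
  220 thyroid voxels). Organs are checked disjoint and inside the grid.
* **Baseline uptake.** Organ voxels are log-normal (location, within-organ
  scale); a per-patient log-space random effect (patient_sd) persists
  across that patient's scans and carries the between-patient variance of
  the percentile biomarker — without it the across-patient SD of SUV_OPT%
  would collapse toward zero for large organs and no realistic normative
  band could exist. Background is clipped Gaussian (mean 0.7, SD
  0.15 g/mL, soft-tissue-like); the volume is smoothed with a Gaussian PSF
  (default FWHM 6 mm) and additive Gaussian noise (SD 0.05 g/mL) is added.
  Log-normality is a modelling choice (SUV is positive and right-skewed);
  no distributional form is implied by the published summaries.
* **Inflammation events.** Diffuse events multiply every organ voxel by
  m(t); focal events multiply one face-connected sub-region covering a
  fraction f (default 0.10) of the organ, grown deterministically from a
  seeded voxel. m(t) ramps 1 → k along a clamped smoothstep over 30 days
  from onset — smoothstep rather than a logistic so the plateau value k is
  reached *exactly*, which keeps the noise-free order-statistics
  identities exact — and decays symmetrically after an optional resolution
  day. The multiplier is applied to the smoothed, noisy image, so the
  composition is exactly `sample_uptake → apply_irae`; this also scales
  the noise inside the lesion, an accepted simplification. Thyroid events
  default to diffuse, bowel/lung to focal, mirroring thyroiditis versus
  segmental colitis/pneumonitis.
* **Cohort defaults** are the published study conditions: 58 patients;
  prevalences 6/58 bowel, 5/58 lung, 9/58 thyroid; baseline ≈ day −36
  (±15 d jitter); follow-ups every ≈ 90 days (±20 d); scans per patient
  2 + Poisson(2) (median 4); onset uniform 20–200 d; peak multiplier k
  uniform 1.8–3.0; clinical lag uniform 14–60 d after imaging onset so
  pre-clinical detectability exists by construction. One master seed
  spawns per-patient streams, so any patient regenerates identically in
  isolation.

### Calibration

`calibrate_baseline` adjusts each organ's location (targets the mean) and
patient_sd (targets the SD) so that simulated irAE-free baseline SUV_OPT%
statistics match targets derived from the published normal ranges by band
inversion (μ = (lo+hi)/2, σ = (hi−lo)/3.92), at the published percentile
per organ (95/95/75). The fixed-point iteration simulates 300 baseline
patients per step and applies damped corrections (damping 0.6); the SD of
an SD estimate at n = 300 is ≈ 4%, so the convergence tolerance of 5%
relative is as tight as one simulation round can verify, and tighter
tolerances cannot converge reliably at this n. `default_uptake_model()`
ships parameters produced by this procedure (refined at n = 600–800) for
the default 4-mm phantom; recalibrate when changing the grid, PSF or
geometry, since smoothing couples organ size to percentile statistics.

### What the simulator does not emulate

Real anatomy and its inter-patient variability; attenuation, scatter and
reconstruction physics; tumour lesions and their response; physiological
confounders (metformin-induced bowel uptake, brown fat); scanner
harmonisation differences; segmentation error in the masks (masks are
exact by construction — segmentation-robustness claims are therefore *not*
exercised by these tests). Passing tests show the statistical machinery
recovers the structure it assumes, not that the biomarker works on
clinical images.

## Problem sizes and numerical choices

Simulation-based suites use the default 4-mm phantom (≈ 0.4M voxels,
≈ 23 ms/scan) or a 6-mm variant of identical world geometry where only
relative behaviour matters. Chosen sizes: coverage checks use a 300-patient
normative band evaluated on 1000 fresh patients; focal-pattern recovery
uses 50 cohorts of 20 patients (30% prevalence, onset 20–60 d so events
are visible at the first follow-up); diffuse flatness 10 such cohorts;
lead-time scenarios use monthly scans with clinical lag 45–90 d, so that a
scan always falls inside the onset-to-diagnosis window the scenario is
about. Degenerate inputs are contracts, not accidents: empty organs,
single-class cohorts, baseline-only series and n < 2 normative samples
raise typed exceptions; a value exactly at a band limit or a score exactly
at a threshold is classified by the documented strict/non-strict rule.

## Known limitations

* Percentile selection on diffuse organs is intentionally unstable — AUROC
  is flat in X, so the argmax is noise-driven; consumers should inspect
  the AUROC(X) profile, which the results object always carries.
* The generator's event model is stationary within a patient (no
  treatment-course dynamics beyond ramp/recovery) and events across organs
  are sampled independently, whereas real multi-organ irAE co-occur.
* NIfTI I/O is restricted to axis-aligned (diagonal-affine) grids; oblique
  acquisitions must be resampled upstream.
* The Wilcoxon exact branch is O(C(n, n₁)) and deliberately capped at
  combined n = 12.
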