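# iraequant

Quantitative FDG-PET imaging biomarkers of immune-related adverse events
(irAE) in patients receiving immune-checkpoint inhibitors.

Checkpoint-inhibitor therapy can trigger autoimmune-like inflammation —
colitis, pneumonitis, thyroiditis — in otherwise healthy organs. Because
inflamed tissue takes up more ¹⁸F-FDG, the routine PET/CT scans these
patients already receive for tumour response assessment carry an untapped
signal: organ uptake often rises *before* the toxicity is diagnosed
clinically. `iraequant` implements the whole-organ, percentile-based
quantification of that signal, for imaging scientists and biostatisticians
who want to evaluate or extend it.

## Method

For each target organ (bowel, lung, thyroid) with labelled mask voxels on
an SUV image (SUV = tissue activity × body weight / injected dose, g/mL):

1. **Percentile profile.** Extract SUV_X% — the X-th percentile of the SUV
   distribution over the organ's voxels — on a grid X ∈ {5, 10, …, 95, 100}.
   Percentiles are robust to the few mislabelled voxels that dominate
   SUV_max.
2. **Optimal percentile.** Each patient's score at X is the maximum SUV_X%
   over their on-treatment scans. The biomarker percentile is

       SUV_OPT% = argmax_X AUROC(X),

   where AUROC(X) discriminates patients with irAE of that organ from
   everyone else. Focal inflammation (a short bowel segment, one lung
   lobe) lifts only the top percentiles, so SUV_OPT% lands near 95;
   diffuse inflammation (thyroiditis) shifts the whole histogram and
   leaves AUROC nearly flat in X.
3. **Operating cutoff.** T_OPT maximises Youden's J = sensitivity +
   specificity − 1 on the ROC curve of max SUV_OPT% (rule: score > T ⇒
   irAE-positive). Group differences are tested with Wilcoxon rank-sum.
4. **Normative range.** From baseline (pre-treatment) scans of patients
   who never developed any irAE: CI95 = [μ − 1.96σ, μ + 1.96σ] of
   SUV_OPT%.
5. **Longitudinal monitoring.** Each patient's SUV_OPT% series is flagged
   where it exceeds the band's upper limit; the lead time is the signed
   gap between the first flag and the clinical diagnosis date.

Because the underlying clinical images are not public, the package
includes a synthetic phantom cohort generator (`iraequant.phantom`) whose
baseline uptake is calibrated so irAE-free SUV_OPT% statistics match the
published normal ranges (bowel [1.74, 2.86], lung [0.73, 1.46], thyroid
[0.86, 1.99] g/mL), and whose inflammation events reproduce the
focal/diffuse temporal structure above. Mask-quality metrics (Dice, average
symmetric surface distance) are included for evaluating externally supplied
segmentations.

## Worked example

```python
import iraequant as iq

# simulate a 58-patient phantom cohort with the default prevalences
spec = iq.CohortSpec(seed=42)
profiles, labels, truth = iq.simulate_profile_table(spec)

model = iq.IrAEBiomarkerModel.from_profiles(profiles, labels)
results = model.fit()
print(results.summary())
```

```
irAE percentile-biomarker model
================================================================================
organ: bowel
  SUV_OPT% = 95   AUROC = 0.95   T_OPT = 2.81 g/mL
  sensitivity = 0.86   specificity = 0.98   Youden J = 0.84   rank-sum p = 0.000122
  normal range = [1.71, 2.78] g/mL (n = 42 irAE-free baselines)
--------------------------------------------------------------------------------
organ: lung
  SUV_OPT% = 100   AUROC = 0.98   T_OPT = 1.77 g/mL
  sensitivity = 1.00   specificity = 0.93   Youden J = 0.93   rank-sum p = 0.00149
  normal range = [0.84, 1.90] g/mL (n = 42 irAE-free baselines)
--------------------------------------------------------------------------------
organ: thyroid
  SUV_OPT% = 100   AUROC = 0.92   T_OPT = 3.17 g/mL
  sensitivity = 0.83   specificity = 1.00   Youden J = 0.83   rank-sum p = 0.000862
  normal range = [1.01, 2.58] g/mL (n = 42 irAE-free baselines)
--------------------------------------------------------------------------------
```

Reading the output: the bowel events in this cohort are focal, so the 95th
percentile is the most discriminative (AUROC 0.95), and a patient whose
maximum on-treatment bowel SUV_95% exceeds 2.81 g/mL is classified
irAE-positive at 86% sensitivity / 98% specificity. The thyroid events are
diffuse, so AUROC is nearly flat in X and the selected percentile is
essentially arbitrary — exactly the behaviour that motivates reporting the
whole AUROC(X) profile (`results.percentile_scans`). Longitudinal
monitoring then flags excursions above each normal band:

```python
monitor_table, report = results.monitor()
print(report["frac_flagged_before_clinical"])   # e.g. 0.35 under 90-day scan intervals
```

A command-line interface mirrors the library
(`iraequant simulate|quantify|select|normative|monitor|report|pipeline`);
`iraequant pipeline --cohort-dir <dir>` writes biomarker JSON, normal-range
JSON, a monitor CSV and the four figure families (AUROC-vs-percentile, ROC
with operating point, dichotomised strip plot, longitudinal series with
grey band).

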