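# adchist

Quantitative analysis of apparent diffusion coefficient (ADC) histograms
in rectal-tumor diffusion-weighted MRI (DWI), built around one practical
question: can a quick, *non-precise* circular delineation with a wide
margin — drawn in seconds by a non-expert — replace careful whole-volume
tumor tracing for ADC measurement, if histogram post-processing is used
to filter out the surrounding tissues that the sloppy region inevitably
includes?

The package is aimed at researchers in quantitative imaging who want a
fully testable, ground-truthed implementation of this measurement chain.
Because patient DWI of this kind is not publicly available, the package
ships a synthetic phantom cohort generator with known per-voxel truth,
so every stage — fitting, feature extraction, agreement statistics,
subgroup testing — can be validated end to end.

## What it computes

**ADC mapping.** DWI signal decays mono-exponentially with the
diffusion weighting *b* (s/mm²):

    S(b) = S0 · exp(−b · ADC)

Voxelwise ADC (mm²/s) is estimated by ordinary least squares on
(b, ln S) across all b-values (default 0, 25, 50, 100, 500, 1000 s/mm²),
dropping non-positive signals and clipping negative estimates to zero.

**Histogram metrics.** For a volume of interest (VOI) the first-order
feature set: min, max, mean, median, SD, skewness, kurtosis (Pearson
convention, normal → 3), every 5th percentile (5th–95th), and VOI volume
in cm³. ADC values are reported on the ×10⁻³ mm²/s scale.

**Agreement.** The intraclass correlation for absolute agreement of
single measures under a two-way model, ICC(A,1), computed from the ANOVA
mean squares

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

plus Bland–Altman bias and 95 % limits of agreement. A *percentile
sweep* then searches all non-precise histogram metrics for the best
surrogate of the precise-delineation mean ADC (the reference standard),
scoring each candidate by ICC(A,1) over the four reader pairings.

**Prognostic comparisons.** Each metric is compared between binary
outcome subgroups (nodal stage, mesorectal fascia involvement,
differentiation, response, metastases) with a Welch t-test when both
arms pass Shapiro–Wilk, otherwise Mann–Whitney U, and Holm–Bonferroni
correction within each outcome family.

**Phantom.** Ellipsoidal tumors (ADC 1.44 ± 0.40 ×10⁻³ mm²/s within a
case) surrounded by rectal wall/pelvic soft tissue, suppressed fat, a
near-zero-signal lumen, and a high-ADC bladder; Rician signal noise; two
simulated readers per delineation style; binary outcome labels whose
only true imaging signal is on tumor volume.

## Worked example

```python
from adchist import RunConfig, cohort_metrics
from adchist.agreement import interreader_table, percentile_sweep
from adchist.voimetrics import average_readers

cfg = RunConfig(master_seed=1)          # 37 simulated patients
metrics, labels = cohort_metrics(cfg)   # one row per (case, method, reader)

avg = average_readers(metrics)
precise = avg.xs("precise", level="method")
nonprecise = avg.xs("nonprecise", level="method")
print(precise["mean"].mean(), nonprecise["mean"].mean())
# 1.4349129507208152 1.5653062205089516

sweep = percentile_sweep(metrics[metrics.method == "precise"],
                         metrics[metrics.method == "nonprecise"])
print(sweep.best_metric, sweep.best_icc_range)
# p40 (0.7177048897840717, 0.7582442247843424)

print(interreader_table(metrics, metric_names=["mean"]).round(2))
#       icc_precise  icc_nonprecise  icc_between
# mean          1.0            0.99         0.47
```

Reading: the sloppy delineation inflates the cohort mean ADC from 1.43
to 1.57 ×10⁻³ mm²/s because it includes higher-diffusing surrounding
tissue, and its mean agrees poorly with the reference (ICC 0.47) even
though readers agree almost perfectly within each method. The 40th
percentile of the non-precise histogram, however, recovers the precise
mean with ICC ≈ 0.72–0.76 — the central working result: a
below-median percentile compensates for the contamination.

The same pipeline is available from the shell:

```
adchist run-all --out run/ --seed 1
adchist fit --dwi case_001_dwi.nii.gz --bvals case_001.bval --out adc.nii.gz
```

`run-all` writes the cohort NIfTIs, `metrics.csv`, `sweep_table.csv`,
`agreement.json`, `outcome_table_<method>.csv` and a manifest; reruns
with the same seed are bit-identical.

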