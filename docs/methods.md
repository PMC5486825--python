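# Methods

## Signal model and ADC estimation

Every voxel of a diffusion-weighted series is modelled as a
mono-exponential decay, S(b) = S0·exp(−b·ADC), with b in s/mm² and ADC
in mm²/s. The default estimator regresses ln S on b by unweighted
ordinary least squares over all b-values with positive signal. This is
the simplest estimator consistent with clinical console behaviour; a
voxelwise nonlinear least-squares refinement (initialised from the OLS
solution) is available via `method="nls"` for sensitivity checks, and on
noiseless data the two coincide.

Numerical choices:

* b-points with non-positive signal are dropped rather than
  invalidating the voxel; a voxel is invalid only when fewer than two
  positive points remain (the map stores 0 and flags it).
* A fitted positive slope (signal rising with b, typical of pure-noise
  voxels) gives a negative ADC estimate, which is clipped to 0 and kept
  valid: ADC is physically non-negative, and this is why contaminated
  regions show minima of exactly 0 on the ×10⁻³ scale.
* All internal computation is float64; noiseless phantom input is
  recovered to ≲ 1e-12 relative error (the acceptance suite requires
  < 1e-10).

## Histogram metrics

Within a VOI the value sample consists of the ADC values of mask voxels
with a valid fit, reported in ×10⁻³ mm²/s. Conventions (each switchable
where noted):

* SD uses the n−1 denominator.
* Skewness and kurtosis are population moment coefficients, m₃/m₂^1.5
  and m₄/m₂²; kurtosis is non-excess (normal → 3), the convention under
  which soft-tissue ADC histograms read 3–4. `bias=False` switches to
  the small-sample-corrected variants; with VOIs of hundreds of voxels
  the difference is negligible.
* Percentiles interpolate linearly between order statistics
  (`numpy.percentile(..., method="linear")`); the method string is a
  parameter.
* The VOI volume counts *all* mask voxels (delineation is what is being
  measured), while `n_voxels` counts only the sampled valid-fit voxels.
  With magnitude (Rician) data every voxel yields a valid fit, so the
  two coincide in practice.
* Voxel volume uses the centre-to-centre slice spacing: 5 mm thickness
  + 0.5 mm gap = 5.5 mm, with 1.82 × 2.26 mm in-plane spacing, i.e.
  22.6 mm³ per voxel by default.

## Agreement statistics

`icc_absolute_single` implements ICC(A,1) — two-way model, absolute
agreement, single measures — directly from the two-way ANOVA mean
squares (subjects × raters, complete matrix). The point estimate is
identical under the mixed and random two-way models, so one computation
serves both. Degenerate inputs: a matrix whose cells are all equal has
no defined ICC and raises; identical rater columns over varying
subjects give exactly 1 from the formula. The implementation is checked
against an explicit sum-of-squares oracle (and against pingouin's
ICC(A,1)) to 1e-10 on randomly generated matrices.

Bland–Altman uses d = x − y, bias = mean(d), limits bias ± 1.96·sd(d)
with the n−1 SD.

The surrogate sweep scores every candidate non-precise metric (mean,
min, max, median, and each 5th percentile) against the precise-method
mean ADC: for each of the four (precise reader, non-precise reader)
pairings an ICC(A,1) is computed over cases, and candidates are ranked
by the pair-averaged ICC. Ties — which occur only in degenerate
constructions — resolve toward the percentile nearest the 50th, then
the lower one, then fixed candidate order, making the sweep fully
deterministic. The between-method entries of the per-metric agreement
table average the two readers within each method before comparing
methods (a flag switches to averaging the four single-reader
cross-method ICCs).

## Subgroup comparisons

For each binary outcome, each metric of the tested subset (volume, min,
max, mean, median, SD, skewness, kurtosis, 5th/30th/45th/70th/95th
percentiles — 13 metrics) is compared between arms. The test is chosen
per comparison: Welch's t when both arms pass Shapiro–Wilk at α = 0.05
(Welch rather than pooled, as the safer default under unequal
variances), otherwise two-sided Mann–Whitney U; arms below 3
observations or with zero spread route to the rank test, and two
identical constant arms report p = 1. `force_test` overrides the gate
in either direction. Holm–Bonferroni is applied within each outcome
family (13 tests) separately per delineation method; the step-down
adjustment is implemented directly and verified against both a literal
brute-force enumeration and statsmodels. Outcomes with an arm of fewer
than two cases are skipped with a logged reason.

## The phantom: what it emulates

Each case is a 64 × 64 × 20 grid at 1.82 × 2.26 × 5.5 mm. From inside
out: an ellipsoidal tumor (semi-axes uniform in 7–13 / 7–13 / 6–12 mm,
volume of order 3 cm³), a 4 mm rectal-wall shell, a 12 mm shell of
adjacent soft tissue (normal wall, muscle, pelvic organs), suppressed
mesorectal fat beyond, a low-signal lumen (radius 3–4.5 mm) carved
through the tumor centre, and a bladder placed anterior at a random
0.5–3 mm gap from the tumor surface. Tissue parameters (S0 in arbitrary
signal units; ADC mean ± SD in 10⁻³ mm²/s):

| tissue        | S0   | ADC           | role in the VOI               |
|---------------|------|---------------|-------------------------------|
| tumor         | 1000 | 1.44 ± 0.40   | the measurement target        |
| rectal wall   | 900  | 1.70 ± 0.55   | dominant margin contaminant   |
| soft tissue   | 800  | 1.60 ± 0.50   | outer margin contaminant      |
| bladder       | 1200 | 3.00 ± 0.30   | high tail / maximum           |
| lumen, air    | 5    | ≈ 0           | near-zero minimum             |
| fat (SPAIR)   | 60   | 0.30 ± 0.10   | noise-floor voxels            |

Per-voxel truth ADC is drawn from the tissue normal clipped below at
1e-5 mm²/s; the tumor mean additionally receives a per-case shift of
SD 0.22 ×10⁻³ mm²/s, the between-patient variation that gives the
agreement statistics a subject variance to detect. Signals follow the
inverse decay model plus Rician noise (σ = 15, i.e. 1.5 % of tumor S0;
at this SNR the fitted tumor-mean ADC bias is well under 2 %, verified
by Monte-Carlo in the test suite).

Delineations: *precise* masks are the tumor label set eroded by a
smooth per-reader random depth field of magnitude `reader_jitter`
(default 0.8 in-plane voxels, capped at twice that), emulating
boundary-tracing variability without touching intensities — reader
Dice ≈ 0.87, within-method ICC of the mean ADC ≈ 0.99. *Non-precise*
masks are, per slice, the filled bounding ellipse of the tumor
cross-section expanded by `margin_mm` (default 5.0, per-reader factor
U(0.95, 1.05) plus small per-slice jitter), unioned with the
cross-section so containment survives discretisation; masks clipped at
the grid edge proceed with a warning.

Outcome labels: nodal stage and fascia involvement are Bernoulli with
probability expit(logit(base) + effect·z) where z is the within-cohort
z-score of log tumor volume (bases 0.70 and 0.38; default effect 2.0,
fixed after a Monte-Carlo power check so that the volume row survives
Holm correction in the large majority of 37-case cohorts).
Differentiation, response and metastasis labels are independent
Bernoulli (0.15, 0.40, 0.22). Volume is thus the only feature carrying
true prognostic signal; note that extreme-order metrics (min, max, low
percentiles, SD) are still weakly coupled to volume through the number
of sampled voxels — a genuine property of order statistics, visible as
occasional isolated rejections.

### Calibration of the defaults

Three phantom parameters were calibrated once, by simulation, to match
the emulated study conditions, and then frozen: the margin (5.0 mm)
sets the non-precise/precise volume ratio to ≈ 3; the reader jitter
keeps within-method ICCs ≥ 0.97; and the contaminant spread (wall
1.70 ± 0.55) reproduces the characteristic non-precise histogram —
broad (SD ≈ 0.6), mean elevated by ≈ +0.1 ×10⁻³ mm²/s, a small
near-zero tail — under which the best surrogate for the precise mean is
consistently a percentile in the 35th–45th range, strictly better than
the non-precise mean itself.

### What the phantom does not emulate

No realistic pelvic anatomy (geometric primitives only), no EPI
distortion or susceptibility artifacts, no perfusion (IVIM)
contribution at low b-values, no intensity differences between readers,
and no missing outcome data. Passing tests therefore demonstrate the
correctness and internal consistency of the measurement chain and the
qualitative contamination/surrogate/prognosis behaviour — not
performance on clinical images.

## Problem sizes

The test suite and the acceptance script use the default cohort size of
37 cases on the 64 × 64 × 20 grid; replicate-cohort studies (power and
family-wise error) use 20 replicates. Unit tests use a reduced
48 × 48 × 14 grid with 6–8 cases.

## Known limitations

* The non-precise minimum is exactly 0 in every contaminated VOI
  (clipped noise-floor fits), so its within-method ICC is undefined and
  reported as NaN rather than a number.
* ICC confidence intervals are not computed (point estimates only), and
  no alternative agreement coefficients (Lin, Krippendorff) are
  provided.
* The sweep searches first-order metrics only; no texture features.
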