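# nawmperf

Perfusion analysis of **normal-appearing white matter (NAWM)** in
longitudinal multiple-sclerosis MRI cohorts, built around dynamic
susceptibility contrast (DSC) bolus tracking, plus a calibrated synthetic
cohort generator that makes every stage testable end-to-end without any
patient data.

The package is for researchers who want a reproducible reference
implementation of a classic DSC-MS analysis chain — indicator-dilution
curve fitting, NAWM histogram summaries, inflammatory-group
stratification, and longitudinal mixed models — or who need a seeded
synthetic DSC cohort with known ground truth to validate their own
perfusion tooling.

## The model

Each voxel's contrast concentration during bolus passage follows the
local-density random walk (LDRW) indicator-dilution model,

```
C(t) = A e^λ √(λ / (2π μ (t−t0))) · exp(−(λ/2)((t−t0)/μ + μ/(t−t0)))   t > t0
```

a generalized-inverse-Gaussian-shaped curve with area `A`, scale `μ`,
skewness `λ` and arrival time `t0`. The perfusion maps follow as

* `CBV = A` (ml/100g; semi-quantitative — no arterial input function),
* `MTT = μ(1 + 1/λ)` (s, the first moment of the transit-time density),
* `CBF = 60·CBV/MTT` (ml/100g/min, central volume theorem),
* `TTP` = time of the fitted curve's maximum.

NAWM is the white-matter probability map thresholded at 0.70 minus the
T2 lesion mask dilated by 2 voxels; CBV/CBF are summarized per visit by
256-bin normalized histograms. Subjects with ≥ 1 newly emerged
contrast-enhancing lesion in ≥ 3 of 4 monthly scans form the
high-inflammatory (HI) group; group and time effects are estimated with
linear mixed models (subject random intercept, REML, Wald intervals),
log-transforming skewed lesion volumes and reporting marginal group means
and percentage changes. See `docs/methods.md` for the full account.

## Worked example

`examples/01_bolus_curve_fit.py` fits one noisy bolus curve on the DSC
grid (TR = 1.92 s, 50 volumes, injection at the 10th image):

```
 param     true   fitted
     A    7.600    7.497
    mu    9.820   10.054
   lam    5.000    5.308
    t0   17.280   17.168

CBV  = A            =   7.50 ml/100g
MTT  = mu(1 + 1/lam) =  11.95 s
CBF  = 60 CBV / MTT  =  37.65 ml/100g/min
r^2 = 0.9287
```

The area (the CBV surrogate) is recovered to ~1%; `μ`, `λ` and `t0`
scatter more because only ~10 samples carry bolus signal at this TR.

`examples/03_cohort_pipeline.py` pushes a small synthetic cohort through
the full disk pipeline (synthesis → quantification → NAWM metrics →
statistics) and prints, among other tables:

```
marginal group means:
 outcome group  estimate  ci_low  ci_high
cbv_nawm    HI      8.38    7.35     9.42
cbv_nawm    LI      8.21    7.17     9.24
cbf_nawm    HI     44.22   39.50    48.94
cbf_nawm    LI     36.58   31.86    41.29

CBV time effects (reference MRI-1):
         term   beta  ci_low  ci_high   p
C(visit)[T.2] -0.196  -0.248   -0.144 0.0
C(visit)[T.3] -0.569  -0.621   -0.517 0.0
C(visit)[T.4] -0.882  -0.934   -0.830 0.0
```

The marginal means are model-based group averages over visits at
covariate means; the visit coefficients are the NAWM CBV decline relative
to the first scan (the generating offsets are 0, −0.2, −0.6, −0.9
ml/100g). With only 8 subjects the group contrast is noisy; at the
default cohort size (33 subjects, 13 HI) the generating means 9.1 vs 7.6
ml/100g are recovered closely (see below).

The same stages are available from the shell:

```
nawmperf synth --seed 1 --out cohort/
nawmperf quantify --cohort-dir cohort/
nawmperf metrics  --cohort-dir cohort/
nawmperf stats    --long-table cohort/long_table.csv --out results/
nawmperf all --seed 1 --out run/          # everything in one step
nawmperf replicate --seeds 1-20 --out replicates.csv
```

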