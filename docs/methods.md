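# Methods

`nawmperf` reimplements, as a tested pipeline, a quantitative DSC-MRI
analysis of normal-appearing white matter (NAWM) perfusion in
relapsing-remitting multiple sclerosis: bolus-tracking quantification with
the local-density random walk (LDRW) indicator-dilution model, NAWM
masking with histogram summarization, stratification of subjects into
high-/low-inflammatory groups by new contrast-enhancing lesions, and
longitudinal random-intercept models. Because no patient data accompany
the analysis, every stage is exercised on a synthetic cohort generator
whose defaults encode the study conditions; this note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## The LDRW bolus model

A voxel's contrast concentration during bolus passage is modelled as

    C(t) = A e^lam sqrt(lam / (2 pi mu (t - t0)))
           exp(-(lam/2) ((t - t0)/mu + mu/(t - t0)))  for t > t0, else 0.

The shape factor is a generalized inverse Gaussian density (index 1/2), so

* integral over (t0, inf) = `A`  — the CBV surrogate;
* first moment about `t0` = `mu (1 + 1/lam)` — the mean transit time (MTT);
* mode at `t0 + mu (sqrt(1 + 1/(4 lam^2)) - 1/(2 lam))` — the basis of the
  time-to-peak (TTP) check.

CBF follows from the central volume theorem, `CBF = 60 CBV / MTT`
(ml/100g/min when CBV is in ml/100g and MTT in seconds). No arterial
input function is used and no deconvolution performed, so CBV/CBF are
semi-quantitative: comparable within a cohort acquired under one
injection protocol, not across methods. The concentration-conversion
constant and the CBV scale constant are fixed at 1 so the generator and
the quantifier share one unit convention.

## Quantification chain

1. **Baseline**: S0 is the mean of volumes 2 … bolus_start_index−1
   (0-based); the first two volumes are dropped by the usual
   T1-saturation convention. Non-positive S0 invalidates the voxel.
2. **Concentration**: `C(t) = -(1/te) ln(S(t)/S0)`. Negative samples from
   noise are kept unclipped so the least-squares noise model stays
   unbiased; any non-positive signal sample invalidates the voxel.
3. **Slice timing**: slice *s* of an ascending single-shot EPI acquisition
   is sampled at `t_k = k TR + s (TR/n_slices)`; every slice is fitted on
   its own grid, which is all the slice-time correction the model needs.
4. **Fitting**: bounded nonlinear least squares of the LDRW model.
   Initialization is by moments of the positive part of the curve
   (area → A0; 10%-of-peak crossing → t0; first moment and variance →
   mu0, lam0 with lam0 clamped to [0.5, 50]). Bounds: A ∈ (0, 100 A0],
   mu, lam ∈ [0.1, 100], t0 ∈ [0, t_peak]. The single-curve reference path
   uses scipy's trust-region-reflective solver; map computation uses a
   batched Levenberg–Marquardt with analytic Jacobians that solves every
   voxel's 4×4 normal equations simultaneously (adaptive per-voxel
   damping, bound projection, step- and cost-stall stopping). A test
   asserts the two agree; noiseless round trips recover parameters to
   ~1e−13 relative.
5. **Maps**: CBV = A, MTT = mu(1+1/lam), CBF = 60·CBV/MTT (exact identity
   by construction), TTP by 0.01-s-grid argmax of the fitted curve in a
   window bracketing the analytic mode (the curve is unimodal, so the
   bracket is exact; the grid search survives a future model swap).
   Voxels are kept when the fit converged with r² ≥ 0.5 — the source
   analysis states no quality criterion, so this threshold is this
   package's own, and at the default noise level it retains >99% of WM.

## NAWM metrics

NAWM = (WM probability ≥ 0.70) minus the T2 lesion mask dilated by 2
voxels. "Dilated by 2 voxels" is read as two iterations of 6-connected
(face-neighbour) morphological dilation — the most conservative common
reading — and the structuring element is 3D. Perfusion maps are
summarized over NAWM by a 256-bin normalized histogram spanning the
per-visit [min, max] (no fixed range is imposed); the histogram mean is
extracted, but the direct arithmetic mean is carried alongside, feeds the
statistics, and is guarded by the invariant that the two agree within half
a bin width. Lesion volumes are voxel counts times voxel volume; enhancing
lesions are counted as 26-connected components, and a component is *newly
emerged* iff it shares no voxel with the previous visit's enhancing mask
(at the first scan, every component counts as new).

## Statistics

* Stratification: high-inflammatory (HI) iff ≥ 1 new enhancing lesion in
  ≥ 3 of the 4 monthly scans.
* Baseline comparisons: pooled-variance t-tests; chi-squared without
  continuity correction for sex (the convention is fixed and documented,
  not inferable from the source).
* Longitudinal models: linear mixed models with a subject random
  intercept, REML estimation, Wald 95% intervals (statsmodels MixedLM),
  visit categorical with MRI-1 as reference. Unbalanced panels are
  retained. Right-skewed lesion volumes are modelled as ln(x + 0.001 mL);
  the offset for zero volumes is this package's choice. Log-scale visit
  coefficients are reported as percentage change, (1 − e^β)·100, with
  order-reversing interval transforms.
* Adjusted perfusion models enter group, T2/T1/Gd lesion volumes, WMV,
  GMV, EDSS, categorical visit, age and sex simultaneously (one joint
  model per outcome); "time" enters categorically. No group-by-time
  interaction is included in the primary models (available as an option).
* Marginal group means: the fixed-effect prediction per group with visit
  levels equally weighted and all other covariates at their sample means;
  delta-method intervals from the fixed-effect covariance.

## The synthetic cohort generator

The generator emulates a 33-subject, 4-monthly-visit cohort with 13
latent HI subjects on a 64×64×27 grid of 1.9×1.9×4 mm voxels (the DSC
geometry). Defaults are the study conditions; none of them is a tuning
knob.

* **Phantom**: concentric ellipsoids — brain mask, cortical GM shell, and
  a WM core whose probability falls off smoothly (~3000 voxels ≥ 0.70,
  ~2300 ≥ 0.90 at default scale). It stands in for structural
  segmentations; no gyral anatomy is modelled.
* **Perfusion truth**: per-visit NAWM mean = group marginal mean −
  mean(visit offsets) + visit offset + subject intercept
  (SD 0.8 ml/100g CBV, 4.0 ml/100g/min CBF). Marginal means 9.1/7.6 and
  43.7/38.7; visit offsets (0, −0.2, −0.6, −0.9) and (0, −1.0, −3.5,
  −5.1). The second-visit offsets are interpolated: the decline is
  reported as monotone with printed third- and fourth-visit coefficients,
  and the second visit as non-significant, so a small intermediate value
  is the consistent choice. CBV and CBF intercepts are drawn
  independently; no perfusion–EDSS causal link is encoded (the observed
  EDSS association cannot be attributed causally from summary results).
* **Rendering**: every WM voxel draws CBV and CBF around the visit truth
  with 5% fractional SD, derives `mu` from the central-volume identity
  with lam fixed at 5 (one nuisance shape keeps recovery attributable to
  A and mu), t0 = 9·TR, and emits S = 100·exp(−te·C) plus 1%-of-baseline
  Gaussian noise on the slice-shifted grid. Only the product of echo
  time, relaxivity and concentration is identifiable, so `te` acts as the
  effective contrast scale; the default 0.15 puts peak WM signal drops at
  ~25–35%, the conditioning of a standard 3T DSC exam (at weak contrast
  the voxel fit becomes SNR-limited rather than estimator-limited).
  Gray matter carries baseline only — GM perfusion is out of scope.
* **Lesions**: chronic T2 lesions are connected quasi-spherical voxel
  balls grown in the WM core from truncated-normal volume draws around
  the group means (5.47/3.07 mL), with a whole-lesion subset forming the
  T1-hypointense mask (0.46/0.92 mL). Enhancing (Gd) lesions comprise one
  prevalent component per subject with enhancing activity, whose volume
  decays by the retention factor 0.391 per visit and shrinks
  concentrically (each visit's extent nests in the previous one), plus
  transient 1–3-voxel incident components realizing the per-visit
  new-lesion counts, placed with a one-voxel 26-connectivity margin so
  component counting reproduces the generated counts exactly. Incident
  counts are Poisson(rate) for rates < 1 (LI default 0.15/visit) and
  1 + Poisson(rate − 1) for rates ≥ 1 (HI default 1.5/visit): the shifted
  form preserves the expected count while making the HI criterion hold by
  construction, which a plain Poisson at rate 1.5 does not (it qualifies
  only ~78% of subjects). The prevalent lesion counts as new at MRI-1
  (all-new convention), so expected first-visit new counts are rate + 1
  for LI subjects; the configured rate governs incident lesions at
  follow-up. The prevalent-decay structure is what lets the log-scale
  mixed model recover the visit-2 percentage decrease near its analytic
  value: with fully zero-inflated enhancing volumes the coefficient is
  structurally attenuated toward zero by the subjects at zero in both
  visits. Voxel quantization (14.4 µL/voxel) still attenuates the
  recovered decrease by a few points at low-volume visits.
* **Covariates**: age, sex, disease duration, EDSS (half-point scale,
  truncated to the group ranges), and normalized GMV/WMV are drawn around
  the group summary values; they influence nothing downstream except
  through the models that adjust for them.

### What the generator does not emulate

No head motion, EPI distortion, registration error, scanner drift,
arterial input variability, bolus dispersion, leakage effects,
gray-matter perfusion, or lesion-perfusion coupling. Passing tests
demonstrate that the pipeline recovers known effects from data satisfying
its own assumptions — an internal-consistency result, not evidence about
robustness to the artifacts real DSC data carry.

## Numerical choices and degenerate inputs

* Histogram ranges narrower than float resolution at 256 bins (zero-noise
  runs) collapse to a single occupied bin at the sample value.
* All-zero or signal-free curves return non-converged fits and are
  excluded from maps rather than raising.
* Truncated-at-zero normal draws use the renormalized truncated
  distribution, which raises means above the nominal value when the CV is
  large (visible for LI T1 volumes); volumes act only as covariates.
* T2 lesion placement reserves 60 core voxels so enhancing lesions can
  always be placed on small phantoms; heavy-tailed volume draws are capped
  to the available core.
* All randomness flows from named integer seeds through
  `numpy.random.SeedSequence`; fixed configuration means bit-identical
  outputs, including across the in-memory and file-based paths (white
  matter noise is drawn before background noise with a fixed call shape so
  both rendering modes give identical WM signals).

## Problem sizes

Replicate studies run 20 seeded cohorts × 33 subjects × 4 visits at
phantom scale 64×64×27 with fitting restricted to the NAWM mask
(~1600–2300 voxels/visit); voxelwise fits are independent, so this equals
full-WM fitting followed by masking. One cohort takes ~30–40 s on one
core, dominated by the batched Levenberg–Marquardt step.

## Known limitations

* Semi-quantitative perfusion units: absolute values are meaningful only
  relative to the shared convention of generator and quantifier.
* The recovered HI fraction sits ~3 points above 39% because roughly 5% of
  low-inflammatory subjects cross the stratification threshold by chance
  under their incident-lesion rate; this is a property of the rate
  calibration, which reproduces the split and significance pattern rather
  than unpublished per-patient counts.
* MTT estimates carry a small upward bias at default noise (lam and mu
  trade off along the curve's flat direction); CBV and CBF, the analysed
  outcomes, are unbiased to well under 1%.
* The mixed models assume Gaussian residuals; the log-offset for zero
  lesion volumes (0.001 mL) makes the visit-2 percentage decrease depend
  mildly on mask quantization at small volumes.
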