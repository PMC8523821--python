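# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `brainagebp`.

## The synthetic cohort generator

The generator is the package's substitute for the (non-public) study data:
it produces cohorts with the statistical structure the analysis assumes, so
that every downstream stage can be exercised and the estimators' recovery
properties measured. Defaults describe the study design the package
targets; each is configurable in `SimulationConfig`.

**Design.** `n_ma = 335` middle-age (baseline age uniform on 44–46) and
`n_oa = 351` older-age (60–64) subjects; up to 4 waves nominally 4 years
apart. Visit intervals get N(−0.16, 0.97) jitter per interval so total
follow-up over three intervals averages 11.5 years (SD ≈ 1.7). Attrition is
missing-completely-at-random: per-wave dropout hazards (0, 0.26, 0.57)
produce ≈ 26/42/32% of subjects with 2/3/4 visits. Sex is Bernoulli per
cohort (52% / 46% female).

**Blood pressure.** Baseline SBP and DBP are normal per cohort
(SBP 125.4 ± 16.8 / 137.9 ± 17.5 mmHg; DBP 80.8 ± 9.9 / 82.5 ± 10.1) with
the male−female gap (8.0 / 5.0 mmHg) split symmetrically around the cohort
mean; baseline MAP follows from the identity MAP = (SBP + 2 DBP)/3. Each
subject gets an annual MAP slope ~ N(0.8, 0.92) mmHg/yr and an annual SBP
slope ~ N(1.41, 1.49), correlated at 0.7; the DBP trajectory is implied by
the MAP identity. This choice is deliberate: the three published slope
means (MAP 0.8, SBP 1.41, DBP 0.61) are mutually inconsistent with the MAP
formula — (1.41 + 2·0.61)/3 = 0.877 ≠ 0.8 — so the generator honours the
MAP and SBP distributions exactly and lets DBP be implied (mean
≈ 0.50 mmHg/yr). The slope correlation keeps pulse pressure from drifting
negative in 12-year tails; marginal slope distributions are unaffected.
Each measure yields two readings per visit, the latent value plus
independent N(0, 3 mmHg) noise — the within-visit reading correlation is
not identified by any published quantity, so the reading-noise SD is a free
parameter.

**Covariates.** Generated independently given cohort and sex (only
marginal summaries are available to calibrate against): education, BMI
normal per cohort; physical activity and alcohol gamma (right-skewed);
smoking 44.5%, APOE ε4 29.7%, diabetes 6.3%/18.5% per cohort.
Anti-hypertensive medication starts at 8.7%/29.6% per cohort and, once
begun, persists, with a 5%/wave onset rate thereafter. MMSE ~ N(28.8, 0.9)
truncated at 30; neurological flags off by default (the filter stage is
exercised by tests that switch them on).

**Outcome.** BrainAGE is generated from the random-intercept equation with
fixed effects β_MAP = 0.019 yr/mmHg (on MAP − 90), β_time = 0.035,
β_cohort = −0.402, β_sex = −0.837, intercept 0.073, random-intercept SD
3.633 yr and residual SD 1.590 yr. The MAP entering the equation is the one
derived from the simulated readings — exactly the quantity the analysis
later sees, so refitting is a pure parameter-recovery experiment with no
errors-in-variables gap.

**Features.** Scan features are a linear mix of latent factors plus a
scanner offset plus isotropic noise. The first latent factor is the latent
brain age (chronological age plus the generated BrainAGE deviation when
present); remaining factors are age-independent nuisance structure. The
scanner label switches between waves (default: from wave 2), adding a
constant per-feature offset. The generator makes no claim to neuroanatomy:
it produces *learnable* inputs with a controllable age signal,
scanner confound and noise floor. Passing tests therefore demonstrate that
the estimation machinery recovers planted structure — not that it would
attain any particular accuracy on real morphometry.

**Randomness.** Every stage (design, BP, outcome, features) draws from its
own stream derived from `(seed, stage key)`, so adding or rerunning one
stage never shifts another's draws; identical (config, seed) gives
bit-identical tables.

## Blood-pressure rules

All threshold comparisons are strict, following the rules' wording:
hypertensive iff SBP > 140 or DBP > 90 or on medication; optimal iff
SBP < 115 and DBP < 75 (equivalently MAP ≤ 90). Model inputs are centered
at 90 (MAP), 114 (SBP), 74 (DBP) mmHg. Outlier screening flags values more
than 3 sample SDs from the sample mean; the eligibility filter applies it
to baseline MAP within each age cohort (the cohorts differ in mean BP, so a
pooled SD would bias exclusions toward the older cohort; a pooled option
and SBP/DBP variants exist). Note a small-sample fact: the largest
attainable |z| in a sample of n is (n−1)/√n, so a 3-SD rule cannot flag
anything in samples of ten or fewer.

## Eligibility and imputation

Stages run in a fixed order — minimum two available scans; neurological
flag or MMSE < 25 at any visit; baseline BP outliers; missing key baseline
covariates (the adjusted model's covariate list) — each reporting entering
and excluded counts. `em_impute` completes covariates under a
multivariate-normal working model fitted by EM (patterns grouped for
speed), never altering observed cells; the observed-data log-likelihood is
non-decreasing and convergence is declared on its relative change. Binary
covariates are imputed on the continuous scale and thresholded at 0.5.
Single imputation only: the original analysis used one completed dataset,
so no multiple-imputation pooling is provided.

## BrainAGE estimation

**Preprocessing.** Optional gray-matter volumes are Gaussian-smoothed
(σ = FWHM / (2√(2 ln 2) · voxel)) and block-averaged to the target
resolution, which must be an integer multiple of the voxel size — block
means avoid interpolation-scheme ambiguity at this scale. Tissue
segmentation, bias-field correction and nonlinear registration are out of
scope; features may equally be supplied directly as a matrix.

**Scanner orthogonalization** residualizes every feature on scanner
indicators plus intercept. It is idempotent and commutes with feature
scaling. Because scanner changes align with waves, and age grows with wave,
this necessarily removes some genuine age variance along with the scanner
offset — the price the real pipeline pays too.

**PCA.** Basis fitted on training scans only; default k is the smallest
number of components explaining 95% of training variance, capped at
n − 2 (the published pipeline's dimensionality is not stated).

**RVR.** Tipping-style type-II maximum likelihood over a kernel expansion
(linear on PCA scores by default — the original BrainAGE convention — with
RBF and polynomial options): iterate the posterior mean/covariance with
α_i ← γ_i/μ_i², β ← (n − Σγ_i)/‖y − Φμ‖², pruning basis functions when
α_i > 10¹² (the bias is never pruned). Convergence requires both
max |Δ log α| and |Δ log β| below 10⁻⁶ (β alone can still be climbing on
near-noiseless data when the α's have stabilized), with a 1000-iteration
cap and β capped at 10¹². Degenerate cases: constant targets yield a
bias-only model; if every kernel basis function is pruned the model falls
back to predicting the mean. With all α fixed at a shared value the
posterior mean is exactly ridge regression at λ = α/β, which the tests use
as a closed-form oracle. One documented subtlety: on tiny noiseless folds
(two training points) the marginal likelihood admits a finite-β optimum,
so predictions are near-exact (~10⁻³ yr) rather than machine-exact.

**Leave-one-subject-out.** All scans of a subject are held out together —
scan-level folds would leak within-subject information across repeated
scans — and PCA + RVR are refit per fold. A hard audit verifies no scan
ever contributes to its own training fold.

**Bias correction.** The gap (estimated − age) is residualized on age
(slope + intercept, OLS) over the full estimation sample, making the final
BrainAGE exactly uncorrelated with age. Regressing the estimate rather
than the gap would zero the correlation identically; the gap form keeps
the score in deviation units. A train-folds-only correction variant is a
possible extension; the full-sample fit is the default because the
correction is a two-parameter rescaling estimated from hundreds of points,
where refitting per fold buys nothing measurable.

## Association analysis

`fit_lmm` wraps a random-intercept linear mixed model (statsmodels
MixedLM), maximum likelihood by default so nested-model likelihood-ratio
comparisons are valid; REML is available. Wald CIs and p-values per fixed
effect; interaction terms enter as products with the centered BP term;
stratified analyses rerun the same specification on a subset, silently
dropping fixed-effect terms that become constant there (recorded on the
fit's warning list). Non-convergence or singular random effects flag the
fit rather than raising. Medication is a time-varying per-wave covariate.
Welch's unequal-variance t (with a pooled option) and Pearson's χ² without
continuity correction handle group comparisons from printed summary
statistics. Day conversions use 365.25 days/year and report 3 significant
figures.

## Problem sizes used in checks

The replication experiments run at the published design size — 686
subjects, ≈ 2,070–2,100 visits — with 200 simulate-and-refit replicates
for the coefficient-recovery experiment and a single cohort for the slope
calibration. The type-I-error audit uses 500 replicates of 150-subject
cohorts: Wald-z calibration is stable in cohort size, and the smaller
design keeps the audit quick. Unit fixtures use 20–80 subjects and 20–60
features.

## Limitations

* Features are a linear latent-factor construction; no spatial structure,
  no tissue contrast, no site-by-age interactions. Results on them bound
  nothing about real morphometry.
* Dropout is MCAR; informative attrition (sicker subjects leaving) is not
  modelled.
* Covariates are mutually independent given cohort and sex; real
  covariance (e.g. BMI–diabetes) is absent.
* The implied DBP slope (≈ 0.50 mmHg/yr) is below the published 0.61
  because the published slope triple is internally inconsistent with the
  MAP identity (see above); MAP and SBP are matched exactly.
* Published fixed-effect estimates from the real cohort are not
  reproducible targets — the data are unavailable — so all quantitative
  checks are parameter-recovery statements about the generating model.
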