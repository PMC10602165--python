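# Methods

## The models

`mrdoc` implements three bivariate twin structural equation models for an
exposure phenotype X and an outcome phenotype Y, observed in monozygotic
(MZ) and dizygotic (DZ) twin pairs, as explicit covariance-structure
models:

* **DoC** — the Direction of Causation model. Per twin the observed
  variables are X and Y; the causal path g1 (X → Y) is identified through
  the contrast between MZ and DZ cross-twin cross-trait covariances. The
  package fits the unidirectional variant with g2 = 0, the A- and C-factor
  cross-trait covariances free, and the E-factor covariance fixed to 0 (a
  bivariate ACE model is identified with any three of g1, g2, ra, rc, re
  free; this choice mirrors the first factorial design).
* **MR-DoC** — DoC plus one polygenic score PS1 instrumenting X (path b1)
  and an explicit directional horizontal-pleiotropy path b2 (PS1 → Y).
  Unidirectional; identification again requires re = 0.
* **MR-DoC2** — adds a second score PS2 instrumenting Y (path b3), frees
  the reverse path g2 and the E-factor cross-covariance, lets the two
  scores correlate (rf), and fixes b2 = 0. Indirect horizontal pleiotropy
  remains representable through rf·b1 and rf·b3.

Residual phenotype variance decomposes into additive-genetic (A),
shared-environment (C) and unshared-environment (E) parts with the usual
twin structure: across co-twins A correlates 1 (MZ) / 0.5 (DZ), C
correlates 1, E correlates 0. Polygenic scores are themselves additive
genetic, so **MZ co-twins carry identical scores**; the MZ observation
vector therefore contains each score once (an 8-variable MZ covariance
would be exactly singular), while DZ twins each contribute their own score
with cross-twin correlation 0.5. This matches the five-variable MZ layout
(X1, Y1, PS1, X2, Y2) in which the MR-DoC covariance is conventionally
reported.

The reduced form used for assembly: with B the 2×2 matrix of simultaneous
causal paths between X and Y, Λ = (I − B)⁻¹, and Γ the instrument-loading
matrix, each twin's phenotype vector is Λ(Γ·PS + u) with u the summed
A/C/E residuals. All covariance blocks follow; (1 − g1·g2) ≠ 0 is required
and enforced.

## Parameterization and study conditions

Two parameterizations coexist:

* **path style** (`style="path"`): ra/rc/re/rf are correlations of the
  factor pairs, converted internally (CA = ra·√(VA1·VA2), ...). This is
  the natural user-facing scale for single-model work.
* **variance-component style** (`style="varcomp"`): the free quantities
  are the A/C/E variances and *raw* cross-covariances (CA, CC, CE, CF).
  All fitting, and all factorial-study data generation, happens on this
  scale.

The factorial designs fix VA = VC = 0.10 and VE = 1 − VA − VC = 0.80 per
trait (unit residual phenotypic variance) and vP1 = vP2 = 1. The
causal/instrument factor levels are quoted on the variance-fraction (R²)
scale — levels 0.025/0.05 for b1, b2, b3 and 0.02/0.04 for g1, g2
correspond to path coefficients √0.025 ≈ 0.158 … √0.05 ≈ 0.224 and
√0.02 ≈ 0.141 … √0.04 = 0.2, i.e. instruments explaining 2.5–5 % of
exposure variance — and the ra/rc/re/rf levels (0/0.2 varying, 0.2
constant in Design 3, ±0.3 in the misspecification studies) enter as raw
variance-component cross-covariances. Two observations pin these
conventions down: instruments on the path scale land exactly in the
"strong instrument" range 0.16–0.22 that motivated the levels, and the
covariance perturbation induced in MR-DoC by re = 0.3 versus re = 0 is
then exactly 0.300 on the X–Y covariance and 2·√0.02·0.3 = 0.085 on the Y
variance — the canonical check matrix for this model family. Under the
raw-covariance convention CA = 0.2 against VA = 0.1 corresponds to an
A-factor "correlation" above 1; that is legal in the variance-component
formulation (only the total observed covariance must be positive definite,
which holds in every design cell) and is one reason the studies use this
style.

Designs: Design 1 (DoC) varies g1, ra, rc → 2³ = 8 cells; Design 2
(MR-DoC) adds b1, b2 → 2⁵ = 32; Design 3 (MR-DoC2) varies b1, b3, g1, g2,
ra, rc with re = rf = 0.2 fixed → 2⁶ = 64. Sample sizes are 1000 MZ and
1000 DZ pairs per cell, α = 0.05, zero means throughout.

## Exact-data simulation

`exact_mvn_sample` draws arbitrary normal deviates, centers them, whitens
by the inverse Cholesky factor of their own sample covariance and recolors
by the Cholesky factor of the target, so the sample covariance (divisor
n − 1) equals the population covariance to ≈1e-15 and the column means are
exactly zero. Consequences exploited throughout: fitting the generating
model recovers the generating parameters exactly; refitting under a
constraint yields a likelihood-ratio statistic that *is* the
non-centrality parameter (NCP) of the test, with no Monte-Carlo error; and
every result is invariant to the seed (seeds only relabel records, which
is why per-cell seeds are recorded but irrelevant to any statistic).

Measurement error with reliability ρ adds independent noise of variance
Var·(1 − ρ)/ρ to a phenotype. It is injected into the population
covariance (phenotype diagonal entries only) rather than into records;
under exact simulation the two routes produce identical fitted objectives,
and the covariance route is deterministic. The study conditions use
ρ_X = 0.90 and ρ_Y = 0.70 — the outcome noisier than the exposure, the
configuration known to bias DoC-type causal estimates.

## Estimation and power

`fit_ml` minimizes the multigroup normal-theory discrepancy

    F(θ) = Σ_g N_g [ ln|Σ_g(θ)| + tr(S_g Σ_g(θ)⁻¹) − ln|S_g| − p_g ]

over the free variance-component parameters (MZ and DZ jointly, covariance
likelihood with means fixed at zero, S_g with divisor n − 1, N_g = number
of pairs). The N_g multiplier reproduces the raw-record −2lnL differences
up to O(1/n) terms; this is verified numerically against a record-level
likelihood in the test suite.

Numerics: L-BFGS-B with an analytic gradient in Σ
(dF/dθ = Σ_g N_g tr[Σ⁻¹(Σ − S)Σ⁻¹ · dΣ/dθ], dΣ/dθ by central differences
with step 1e-6 on the exact assembly), ftol 1e-15 / gtol 1e-8, one restart
from a perturbed point if the final gradient norm exceeds 1e-3 (on the
N-scaled objective, this corresponds to parameter errors ≪ 1e-5).
Variance components are **unbounded**: misspecified models legitimately
need negative variance estimates, and clamping them at zero would leave
fits stranded on the bound and distort likelihood-ratio statistics;
positive definiteness of the implied covariance is enforced by a penalty
on the objective instead. A soft penalty also keeps |g1·g2| away from the
unit root. Starting values are the generating truth inside the simulation
pipeline (the landscape is smooth and the truth is the natural
neighborhood of every optimum) and {variances 0.3, paths/covariances 0.01}
otherwise; the exact-recovery checks deliberately use the generic start so
that recovery demonstrates identification rather than initialization.

`lrt_ncp` takes F(constrained) − F(full) (clipped to 0 below 1e-8;
negative values beyond tolerance raise — they indicate optimization
failure, not a statistic), and `power_from_ncp` evaluates the noncentral
chi-square tail above the central critical value. At ncp = 0 the power is
the test size by definition and is returned exactly.

## The five scenarios

* **S1** (measurement error, own generator): each model generates its own
  design, error is injected, the same model is refit. DoC and MR-DoC
  underestimate g1 (the error inflates within-twin variances in a pattern
  the re = 0 constraint cannot absorb); MR-DoC2 absorbs independent
  phenotype error *exactly* into its free E block (E enters only the
  within-twin residual covariance, so E′ = E + Λ⁻¹·diag(errors)·Λ⁻ᵀ
  reproduces the degraded covariance with every other parameter untouched)
  and its causal/instrument estimates are exact.
* **S2** (re misspecification, own generator): re = ±0.3 at generation,
  DoC/MR-DoC refit with re = 0 — ĝ1 absorbs the unmodeled E covariance
  with its sign; MR-DoC2 (re free) is exact. MR-DoC's pleiotropy path b2
  picks up a small compensating bias of the opposite sign.
* **S3/S4** (error / re misspecification, MR-DoC2 generator): Design 3
  generates, all three models are fit to the marginal of the variables
  each observes. Biases in DoC/MR-DoC are larger and more pervasive than
  under own-model generation; MR-DoC2 remains exact.
* **S5** (power): Design 3 generates (re = rf = 0.2); for each fitted
  model the 1-df NCP of g1 = 0 is extracted (a 2-df {g1, g2} variant is
  available behind `include_2df`, for MR-DoC2 only) and regressed by OLS
  on the six varying factor levels, with intercept and main effects only;
  the constants re, rf are absorbed by the intercept. R² is reported per
  fitted model, together with slopes and standardized slopes. Because the
  factors are two-level, R² is invariant to the variance-fraction vs path
  scaling of the regressors.

Determinism: exact data makes every scenario a deterministic function of
its configuration; two runs with the same config agree to floating-point
reproducibility, and the master seed only affects raw records, never
summaries.

## What the generator does and does not emulate

The synthetic data are exactly multivariate normal with exactly the
model-implied first two moments. Real twin data depart from this in ways
deliberately out of scope: sampling variability (a real N = 1000 study
scatters around these NCPs), non-normality and ordinal measures, missing
data, assortative mating, sibling interaction, and polygenic scores that
are noisy estimates of true genetic values rather than clean
additive-genetic variables. Passing tests therefore demonstrate the
algebraic/likelihood machinery and the asymptotic bias and power structure
of the estimators — not their finite-sample behavior on real data.

## Known limitations

* The NCP regressions for DoC and MR-DoC explain essentially all NCP
  variance (R² ≈ 0.99) under these conditions, because the unmodeled
  re = 0.2 confound dominates the g1 = 0 statistic nearly additively in
  g1 + g2; the standardized coefficient structure (g1 dominant, ra/rc
  small, b1 nil for MR-DoC) is the robust finding.
* No standard errors, confidence intervals or profile likelihoods; the
  exact-data framework is about population values and NCPs.
* Boundary-adjacent inference (chi-bar-square mixtures) is not applied:
  the tested constraints (g1, g2) are interior parameters.
* DoC fitted to MR-DoC2-generated data is just-identified, so its full-fit
  discrepancy is ~0 and all misfit loads on the constrained fit; this is a
  property of the model, not of the optimizer.
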