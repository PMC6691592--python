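# Methods

## Models

All models are linear latent-variable models over six observed scores (two
domains × three waves, labelled T1–T3) expressed in the RAM
parameterization: directed paths `A` (regressions, loadings), symmetric
exogenous (co)variances `S`, intercepts/means `m`, observed-variable
selector `F`, giving implied moments Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ and
μ = F(I−A)⁻¹m. Equality constraints are encoded by shared parameter
labels; one label = one estimated quantity.

**Measurement layer.** Each observed score loads (fixed 1) on a latent true
score whose observed residual variance is fixed to S²(1 − Rxx), with S² the
sample variance of that variable and Rxx its internal-consistency
reliability. This is the standard single-indicator correction: it cannot
estimate measurement error from one indicator, but removes a known quantity
of it. With no reliabilities supplied, indicators are treated as error-free.

**Bivariate latent change score (LCS) family.** Latent changes are defined
structurally by fixed unit loadings (Y_t = Y_{t−1} + ΔY_t) and regressed on
prior levels: ΔY_t = α_Y + β_Y·Y_{t−1} + γ_{X→Y}·X_{t−1} + ζ. Default
equality constraints across the two transitions: self-feedbacks β, couplings
γ, change residual variances ζ, and the contemporaneous change covariance.
The four lagged change covariances are individually free (each occurs only
once). The first domain's (vocabulary's) change intercept is freed per
occasion by default — conditional vocabulary gains shrink across waves in
data of this kind — with a flag to equate it. This bookkeeping yields 19
free parameters against 27 observed moments, df = 8; the fully equated
variant has df = 9. The **mutualism** model frees both couplings; the
**investment** model frees only reasoning → vocabulary-change (direction
exposed as an argument); the **no-coupling** model fixes both.

**Developmental g-factor model.** One common factor per wave with
measurement invariance (the reasoning loading λ and intercept τ shared
across waves; vocabulary fixes the scale), domain-specific unique variances
equated across waves, and a univariate LCS on g (10 free parameters,
df = 17).

**Parallel-process growth model.** Per domain an intercept factor
(loadings 1,1,1) and linear slope factor (loadings 0,1,2); each slope is
regressed on the *other* domain's intercept. The enumeration that
identifies the model at df = 9: two cross paths, four factor
means/intercepts, two intercept variances, two slope residual variances,
intercept–intercept covariance, slope–slope residual covariance, and six
per-wave true-score residual variances. Intercept–own-slope covariances are
fixed to 0 — the price of freeing per-wave residuals in a 3-wave design —
and the within-domain intercept → own-slope paths (the "Matthew effect"
contrast) are present but fixed to 0 unless requested, adding exactly two
parameters when freed. Directionality note: with three waves, "baseline of
one domain drives rate of change of the other" is the regression the
package fits (slope ← other intercept); the reverse arrow (intercept ←
other slope) describes the same association with a different causal
reading and is not separately identified here.

**RI-CLPM.** Per-domain random intercepts (unit loadings at every wave)
absorb stable between-person differences; within-person components carry
lag-1 autoregressive and cross-lagged paths (equated across the two lags),
wave-specific residual covariances, and free observed means (20 free
parameters, df = 7). No reliability layer: the within components already
absorb occasion-specific variance.

## Estimation

**FIML.** The likelihood is the sum over persons of the multivariate-normal
log-density of each person's observed sub-vector under the matching
sub-matrices of (μ, Σ). Persons are grouped by missingness pattern and
reduced to per-pattern sufficient statistics (n, mean, scatter), so one
likelihood evaluation costs O(#patterns), not O(n). Persons with no
observed scores are excluded with a logged warning — they carry no
information. Analytic gradients follow from d(I−A)⁻¹ = B·dA·B and
accumulation of ∂ℓ/∂Σ, ∂ℓ/∂μ across patterns; they are verified against
central finite differences in the test suite (1e−7 relative).

**Optimizer.** BFGS on the per-person-scaled negative log-likelihood
(gradient supplied), gtol 1e−6; on failure up to 5 restarts from jittered
starting points with a fixed jitter seed, so every fit is reproducible.
Starting values: fixed unit loadings; free variances at half (or a
documented fraction of) the observed variance; paths at 0; means/intercepts
at observed means and mean gains. A run with a precision-loss message but
near-zero gradient is accepted as converged (routine for finite-precision
BFGS at a well-resolved optimum). Non-convergence is flagged in the result,
never silent; negative estimated variances raise a Heywood warning on the
result. Fitting refuses datasets with fewer persons than free parameters.

**Standard errors** come from the inverse observed information (negative
Hessian of the log-likelihood, obtained by differentiating the analytic
gradient). Standardized solutions scale each path by sd(source)/sd(target)
from the implied full covariance (covariances → correlations, variances →
proportions of total); delta-method SEs for standardized estimates use the
numerical Jacobian of the standardization map.

**Saturated and baseline models.** The saturated log-likelihood uses the
unrestricted FIML solution: closed form for complete data, EM over
missingness patterns otherwise (tolerance 1e−10 on the log-likelihood).
The CFI baseline is the independence model (free variances and means, zero
covariances), whose FIML solution separates per variable and is computed in
closed form.

**Fit indices.** χ² = 2(ℓ_sat − ℓ); df = 27 − (free parameters);
RMSEA = √(max(χ²−df,0)/(df·(n−1))) with the 90% CI from inverting the
noncentral-χ² CDF at the 5%/95% points (this n−1 convention reproduces
textbook values exactly); CFI from the independence baseline; SRMR as the
root-mean-square standardized residual of the covariance block only (means
optional by flag); AIC = −2ℓ + 2k, BIC = −2ℓ + k·ln(n). AIC/BIC ties are
reported as ties, never broken silently. LRTs assume the caller's nesting
assertion and flag materially negative statistics instead of truncating
them quietly.

**Multigroup fitting** estimates one spec per group simultaneously;
cross-group equality is expressed by sharing labels, group-specific
parameters by relabelling. The default freed set for the invariance test on
the bivariate LCS specs — initial-status variances and covariance,
self-feedbacks, couplings, change intercepts, change residual variances,
and the contemporaneous change covariance — totals 13 parameters for the
mutualism spec and is configurable.

**Cross-sample comparison** uses z = (β₁ − β₂)/√(se₁² + se₂²) on
standardized estimates by default; a Fisher-transformed variant (with
delta-method SEs) is available for correlation-metric parameters. The two
variants agree to O(β²) relative error; the choice matters only for large
effects. Bundled reference values for the adolescent comparison sample
carry point estimates only, so those rows are reported as "not testable"
unless the user supplies SEs; directional verdicts (couplings expected
stronger, self-feedbacks weaker, in younger samples) are reported
regardless.

## Synthetic data

The generator draws person-vectors from the exact implied multivariate
normal of any specification at chosen true values (Cholesky factorization;
one seeded generator per run, replicate r seeded base_seed + r) and applies
missingness completely at random (MCAR). Two presets fix the package's
documented generating conditions:

- **g-factor preset** — g starts at mean 25, variance 16 (vocabulary
  raw-score units); gains `mean_change` = 4 points per wave plus
  `self_feedback` (default 0.1) times the prior level; reasoning loading
  0.8 with intercept −6; unique variances 6/5; change residual variance 3.
  Variants with self-feedback 0 or negative are supported; raise
  `mean_change` there to keep improvement global.
- **mutualism preset** — wave-1 true-score variances 20 per domain,
  cross-domain correlation .55 (the positive manifold), means 23/14,
  self-feedbacks −0.2 raw (≈ −0.33 standardized), change residual
  variances 6 with contemporaneous residual correlation .3, lagged change
  covariances 0, intercepts solved to give mean gains of ~5 (vocabulary)
  and ~4 (reasoning) points per wave. The shared raw coupling is solved
  numerically (Brent) so the standardized vocabulary → reasoning-change
  coupling at the first transition equals the requested value (attainable
  range [0, 0.5] under these variances).

Both presets make the reliability adjustment self-consistent: with
Rxx = .90, observed variance satisfies V_obs = V_true/Rxx, and the design's
variances are set accordingly. These defaults were chosen once, to sit on
the raw-score scale and correlation structure typical of Wechsler-type
measurements over three annual waves in middle childhood (monotone growth,
positive manifold ≈ .5, moderately negative standardized self-feedback,
positive contemporaneous change correlation).

**What the generator does and does not emulate.** Samples are exactly
multivariate normal, missingness is MCAR only, and the generating model is
always one of the package's own specifications. Passing simulations
therefore demonstrate correctness of estimation and honest calibration of
tests under ideal distributional conditions — they say nothing about
robustness to non-normality (where plain and robustly-scaled ML diverge),
to MAR/MNAR missingness, or to generating processes outside the model
family. Plain (unscaled) ML is the estimator throughout for this reason.

## Simulation experiments

**Model recovery** (default 200 replicates, N = 227): simulate under the
g-factor preset, fit both the g-factor and mutualism LCS models, record the
AIC winner (the models are not nested). Ties are counted separately;
non-converged replicates are excluded from the denominator and reported.
Under these conditions AIC selects the true g-factor model in ≈ 98–99% of
replicates. A structural ceiling applies: the 19-parameter mutualism model
nearly saturates the moment structure the 10-parameter g-factor model can
generate, so the likelihood gain from the extra 9 parameters behaves like a
χ²₉ draw and exceeds the AIC penalty of 18 in roughly 2–3% of samples.
Selection rates meaningfully above that require candidate models whose
implied-moment manifolds overlap less than these two do.

**Power curve** (default 100 replicates per grid point, N = 227, α = .05):
simulate under the mutualism preset across a grid of standardized coupling
strengths, fit the correctly specified mutualism model, and test the
vocabulary → reasoning coupling — Wald z on the raw estimate by default
(the equality-constrained estimate pools both transitions), a 1-df LRT by
flag. Rejection proportions carry exact Clopper-Pearson 95% CIs; grid
points with > 20% non-convergence are flagged unreliable. Under the
documented conditions: type-I error ≈ .03–.05 at coupling 0, power ≈ .21–.28
at .1, ≈ .74 at .2, ≈ .96 at .3 (Wald SEs verified well-calibrated against
the empirical sampling spread). Power at a *standardized* coupling is
governed by the share of change variance explained by prior levels and by
the cross-domain level correlation, not by the coupling alone: designs
described as having much higher power at .1 correspond to generating
processes whose latent changes are far more level-determined (change R²
near 50%) than the fitted estimates typical of raw cognitive scores (R²
≈ 8–15%) support. The replicate counts above keep a full desk run in
minutes; both experiments scale to thousands of replicates by flag.

## Known limitations

- Exactly three waves for the LCS and RI-CLPM builders (the df bookkeeping
  above is wave-count specific); generalizing is an extension point.
- Continuous indicators and plain ML only: no categorical estimation, no
  robust (scaled) test statistics, no multilevel or Bayesian variants.
- Single indicators per domain: "latent" refers to the change scores and
  the reliability-corrected true scores, not a full measurement model.
- The cross-sample comparison consumes published point estimates; without
  reference SEs it reports directions, not tests.
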