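# Methods

## The joint mean–dispersion model

`muacglm` fits a Gaussian response (MUAC, cm) with observation-specific
variance. The mean submodel is an identity-link Gaussian GLM,
μᵢ = xᵢᵗβ, var(yᵢ) = φᵢ; the dispersion submodel treats the Gaussian
deviance components dᵢ = (yᵢ − μᵢ)² as a gamma-family response with log
link, E(dᵢ) = φᵢ = exp(gᵢᵗγ), var(dᵢ) = 2φᵢ². The log link is chosen
because it guarantees φᵢ > 0 and makes the dispersion coefficients
interpretable as multiplicative effects on the residual variance; it is
the standard choice in the double-GLM literature.

Assumptions worth stating explicitly: conditional normality of MUAC given
the covariates; independence across children (a single-clinic cross
section, no cluster structure); variance depending on covariates only
through the log-linear form; and a correctly specified linear mean with
raw (uncentered) pairwise interactions. Collinearity among the raw
interaction columns is substantial by construction (age, weight and
height are strongly correlated); it is reported through the coefficient
covariance, not "corrected", and the design matrix is handled by pivoted
QR so rank deficiency is detected and named rather than silently ridged.

## Fitting algorithm

Alternating IWLS:

1. Initialize φᵢ ≡ RSS/(n − p) from the ordinary least-squares fit.
2. Mean step: weighted least squares with prior weights 1/φᵢ. Identity
   link means one IWLS step is exact. Coefficient covariance is
   (XᵗWX)⁻¹ with no residual scale factor — the dispersion is already in
   the weights.
3. Dispersion step: gamma/log quasi-likelihood IWLS. Under ML the
   response is dᵢ with prior weights 1/2; under REML the response is
   dᵢ/(1 − qᵢ) with prior weights (1 − qᵢ)/2, where qᵢ is the mean-model
   leverage. The 1/2 carries the var(dᵢ) = 2φᵢ² quasi-dispersion, so the
   reported covariance (GᵗWG)⁻¹ needs no further scaling.
4. Update φᵢ and repeat until both |Δ(−2h)| and max|Δβ| fall below 1e−8
   (cap 100 outer iterations; non-convergence returns a flagged result
   with the −2h trace rather than raising).

Under ML weighting the fixed point is a stationary point of the extended
quasi-likelihood −2h = Σ[(y−μ)²/φ + log(2πφ)]; the test suite verifies
this against gradient-based joint maximization. REML is the default
because ML dispersion estimates carry an O(p/n) downward bias that is
material at n ≈ 163 with p = 10; with an intercept-only dispersion model
REML reproduces the unbiased RSS/(n − p) exactly, ML reproduces RSS/n.
Both variants are exposed because the reference likelihood values report
both −2ML and −2RL.

Numerical details: zero deviance components are floored at
1e−10 × mean(d) rather than dropped, keeping the two submodels aligned on
the same n. The inner gamma IWLS iterates to max|Δγ| < 1e−10 with a cap
of 300 iterations — Fisher scoring converges only linearly when the
dispersion model is misspecified for the data at hand, and small
misspecified instances were observed to need ~200 iterations. −2RL adds
log det(XᵗWX/2π), computed by `slogdet` with an explicit singularity
error.

## Model selection

cAIC = −2h + 2·p_mean (mean coefficients only), AIC = −2h +
2(p_mean + q_disp), BIC = −2h + (p_mean + q_disp)·log n. These identities
are exact arithmetic, asserted as such. A leverage-based effective-df
cAIC was considered and not made default: the published criterion values
this package is checked against satisfy cAIC − (−2ML) = 2 × 10 exactly,
i.e. a raw coefficient count. When criteria disagree, the lowest AIC
decides.

The exploratory backward-elimination screen drops, one at a time, the
term with the largest Wald p-value ≥ 0.2, never the intercept, and never
a main effect while one of its interactions survives. Ties break to the
lexicographically smallest label so the outcome is independent of
candidate ordering. The refit procedure is a parameter (default:
constant-dispersion Gaussian GLM) because the choice of screening model
is genuinely open.

Wald p-values use the standard normal by default (the large-sample Z
approximation); Student-t with n − p df is available behind a flag.
Stars: *** p < 0.001, ** p < 0.01, * p < 0.05. The strongest printed
category in the reference tables is labeled "sig at p < 0.00", which is
impossible as written; it is interpreted as p < 0.001, consistent with
the printed t magnitudes.

## Synthetic cohort generator

The generator emulates a cross-sectional malnourished-child cohort whose
raw data are not public, using only its published summary structure:

- **Marginals.** Each covariate is a truncated normal on its observed
  range. Truncation moves moments, so the latent (mean, sd) are solved by
  root-finding so that the *truncated* distribution has exactly the target
  mean and sd (e.g. the latent age distribution is N(−6.98, 4.19²)
  truncated to [0.13, 5], delivering mean 1.6334, sd 1.18655).
- **Dependence.** A Gaussian copula. Marginal transforms attenuate
  correlations, so each latent pairwise correlation is solved by 2-D
  Gauss–Hermite quadrature (48² nodes, Brent root-finding) so the
  delivered Pearson correlation matches its target (age–weight 0.799
  requires latent 0.821). The pairwise-calibrated latent matrix is
  eigenvalue-clipped to positive definite if needed (not needed at the
  defaults).
- **Response.** MUAC = xᵗβ + sqrt(exp(xᵗγ))·ε with standard-normal ε and
  the published coefficient vectors as defaults — so the generated data
  follow the fitted model family exactly and parameter recovery is
  well-posed. Non-positive MUAC draws (~2 in 10⁵ rows at the defaults;
  a circumference must be positive) have their noise redrawn; the
  truncation bias this introduces is orders of magnitude below the
  estimator's standard errors at every n used.

One integer seeds a single `numpy` generator consumed in a fixed order —
latent covariate normals first, then response noise, then any positivity
redraws — so a (seed, config) pair is fully reproducible.

What the generator does **not** emulate: measurement error and digit
preference, missingness, clinic- or season-level clustering, any
non-Gaussian response shape, and gender (absent from the published
coefficient tables; flagged to users rather than invented). Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness of the scientific conclusions to
violations of them.

An inverse-CDF copula was chosen over rejection sampling of a clipped
multivariate normal deliberately: joint rejection changes every marginal
moment (the age mean would shift by ~14%) and attenuates correlations,
which would defeat the generator's purpose of hitting the published
targets; the copula respects the bounds by construction with no boundary
atoms.

## Diagnostics

Standardized residuals are rᵢ = (yᵢ − μᵢ)/sqrt(φᵢ(1 − qᵢ)) — the
standard GLM studentization specialized to the Gaussian family, with the
joint model's fitted φᵢ. The four-panel bundle (residuals vs fitted with
a centered running mean, absolute residuals, normal QQ at plotting
positions (i − ½)/n, equal-width histogram) is computed as plain numbers;
matplotlib is an optional rendering layer. The running mean sorts by
fitted value with ties broken by residual, so all bundle outputs are
invariant to input row order. No formal normality or heteroscedasticity
tests are attached: the bundle supports visual model criticism.

## Problem sizes and test design

The suite checks exact identities at desk scale; estimator equivalences
on 50–163-row instances; parameter recovery at n = 5000 (every mean and
dispersion coefficient within 3 reported SEs of truth); 95% Wald-interval
coverage over 200 replicates at n = 1000 (accepted band [0.90, 0.99]);
AIC preference for the joint model over the constant-dispersion GLM on
100 replicates at n = 1000; and generator calibration at n = 100 000
(means within 2%, age–weight correlation within 0.03). These sizes make
the Monte-Carlo assertions sharp while keeping the whole suite under
half a minute on one core.

## Known limitations

- The alternation is not guaranteed monotone in −2h; damped oscillation
  is tolerated and observed, convergence is declared on joint stability
  of −2h and β.
- Dispersion-model Wald inference is first-order quasi-likelihood; no
  small-sample correction beyond REML leverage adjustment.
- The copula calibration matches pairwise correlations, not the full
  joint dependence; higher-order dependence in real cohorts is not
  represented.
- Units are carried as published (hemoglobin and albumen in the source
  laboratory's units); MUAC can be ingested in mm via a flag but is
  stored in cm.
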