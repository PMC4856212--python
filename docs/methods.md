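# Methods

## Design and estimands

A regression discontinuity design identifies a causal effect when
treatment assignment depends on a continuous score `X` crossing a
threshold `x₀`. With `Z = 1{X ≥ x₀}` (boundary inclusive above — a
record exactly at the threshold belongs to the "above" group) and a
binary treatment `T`, the sharp estimand is the outcome jump at the
threshold and the fuzzy estimand is the instrumental-variable ratio

```
ATE  = E(Y|Z=1) − E(Y|Z=0)
LATE = [E(Y|Z=1) − E(Y|Z=0)] / [E(T|Z=1) − E(T|Z=0)]
```

Since |Δπ| ≤ 1, the LATE always has magnitude at least that of the ATE;
a sign flip would require treatment to be *less* likely above the
threshold and indicates a broken design.

Identification assumptions and how the package treats them:

* **A1, instrument relevance** — testable;
  `test_instrument_association` reports the 2×2 (Z, T) table, the
  treated-proportion difference with a Wald 95% CI and a Pearson
  chi-square, and flags differences below a configurable floor
  (default 0.1) as weak.
* **A4, continuity** — partly testable on observed covariates;
  `covariate_continuity` compares the two threshold-adjacent bins of a
  covariate's binned means.
* **A2 (guideline independence), A3 (unconfoundedness of the
  indicator), A5 (monotonicity / no defiers)** — involve unobserved
  quantities; the assumptions report states that they are untestable
  rather than inventing proxies.

## Local linear models

All estimators are fit within a closed bandwidth window
`|x − x₀| ≤ h` (with an ulp-scale tolerance so that decimal boundary
cases like |0.15 − 0.20| ≤ 0.05 behave as written). Bandwidth choice is
deliberately left to the analyst: `h` is a required parameter and the
CLI fits a sweep (default {0.05, 0.15, 0.25}) as a sensitivity
analysis; no automatic bandwidth selector is provided.

**Outcome (numerator) model.** Two segments in the centred score
`xc = x − x₀`:

```
y_il ~ Normal(β₀l + β₁l·xc, σ²),   l ∈ {b, a}
β₀a = β₀b + φ,      σ ~ Uniform(0, 5)
```

with independent Normal(mean, variance) priors on β₀b, β₁b, β₁a and on
the jump φ (`wip`: N(0, 2); `sip`: N(−2, 1)). The intercept/slope
hyperparameter defaults (m₀ = 3.5, s₀² = 4, slope means 0 with variance
100) are implementation defaults that keep prior-plausible LDL levels
in roughly 1–7 mmol/l over the observed risk range; they are weak and
exposed on `PriorSpec`.

**Treatment (denominator) model.** Counts of treated patients on each
side are binomial, `Σt_il ~ Binomial(n_l, π_l)`, with either
independent Beta(1, 1) priors (`unc`) or the flexible difference prior
(`fdp`), logit(πₐ) ~ N(2, 1), logit(πᵦ) ~ N(−2, 1). No treatment-side
slope is modelled — the denominator is the window-average probability
gap, exactly as in the estimand's binomial formulation.

**Composition.** The two likelihoods share no parameters, so numerator
and denominator are fitted as independent posteriors and paired draw by
draw: `LATE_i = φ_i / Δπ_i`. Draws with |Δπ| below a configurable floor
(default 0.01) are *counted and reported*, never truncated or dropped —
the weak-instrument blow-up is a finding, not a numerical nuisance, and
sanitising it would hide exactly the failure mode the simulation study
is designed to expose.

## Posterior computation

No external probabilistic-programming engine is used; the samplers are
part of the package and exploit the models' structure.

* **Blocked Gibbs for the outcome model.** Given σ, the coefficient
  vector (β₀b, β₁b, φ, β₁a) has an exact multivariate Normal full
  conditional (Normal priors are conjugate); given the coefficients,
  the precision 1/σ² implied by σ ~ Uniform(0, upper) is
  Gamma((n−1)/2, SSE/2) truncated to 1/upper², drawn exactly (plain
  Gamma draw with CDF-inversion fallback when truncation binds). Both
  blocks are exact conditional draws, so mixing is essentially
  immediate; defaults are 4 chains × (2000 warmup + 2000 kept) with
  over-dispersed initialisation around the least-squares fit. Per-draw
  cost is independent of n because the sampler touches only X'X, X'y
  and y'y.
* **Quadrature sampler for the treatment probabilities.** Each π_l
  posterior is one-dimensional: the log density is scanned on a coarse
  grid over (0, 1), the region within 40 nats of the mode is re-gridded
  with 16 385 points, and i.i.d. draws are produced by linear
  inverse-CDF sampling of the trapezoid-rule CDF. Under the Beta prior
  this must reproduce the conjugate Beta(1+s, 1+n−s) closed form, which
  the test suite verifies within 3 Monte Carlo standard errors across a
  grid including s = 0 and s = n; the logit-normal prior runs through
  the identical machinery.

Diagnostics (split-chain R-hat, bulk ESS via ArviZ) are computed per
parameter at fit time; R-hat above 1.05 raises a `ConvergenceWarning`
attached to the run, never a silent pass or a hard error. Seeds: one
user seed per fit is expanded into independent substreams (chains,
π-side samplers) via `SeedSequence.spawn`, so fits are bit-reproducible.

Posterior summaries are means, standard deviations and 2.5/50/97.5%
quantiles with numpy's linear-interpolation quantile rule; they are
exact deterministic functions of the draws.

## Frequentist baseline

`Δβ_freq` fits the same two segments by OLS (statsmodels), one side at
a time; the estimate is the intercept difference, the standard error is
`sqrt(se_b² + se_a²)` (independent samples), and the 95% CI uses the
standard normal multiplier 1.96 — at the sample sizes of interest the t
correction is negligible. The minimum is two records with distinct
scores per side (the smallest identifiable line); a saturated side
contributes zero residual variance, so exact-fit data report se = 0. A
frequentist LATE is intentionally absent from the estimator menu.

## Synthetic cohort generator

The generator produces the study conditions for every test: a cohort
whose structure matches the statin scenario while keeping full control
of the truth. Per subject:

```
X ~ Beta(2, 6)                     risk score; mode ≈0.15, right-skewed
U ~ Normal(0, 1)                   unobserved confounder (HDL role)
Z = 1{X ≥ 0.2}
T ~ Bernoulli(expit(γ₀ + γz·Z + γu·U + γx·(X − x₀)))
Y = 3.5 + 2·(X − x₀) − τ·T + λ·U + ε,   ε ~ Normal(0, 0.8²)
```

Defaults: n = 5720, τ = 2 mmol/l (a *reduction*: the induced jump is
−τ), γ₀ = −2.5, γz = 5 (strong) or 1 (weak), γu = 0.5 (low) or 6
(high), γx = 0.5. The outcome baseline (3.5 mmol/l) and slope
(2 mmol/l per unit risk) keep LDL in a plausible 1–7 mmol/l band; the
residual scale 0.8 gives a total outcome noise near 1 mmol/l.

λ is not a free constant: it is solved exactly per cohort from the
sample-moment quadratic so that the realised corr(U, Y) equals the
configured target (0.18 "baseline", matching the LDL–HDL correlation of
the motivating database, or 0.50 "adjusted"); a failure to land within
±0.05 raises `CalibrationError` with the achieved value. Confounding
levels combine the two channels: 1 = (γu low, 0.18), 2 = (low, 0.50),
3 = (high, 0.18), 4 = (high, 0.50). Note the ordering is per channel:
treatment-side confounding (γu) is non-decreasing across the tiers and
outcome-side correlation is non-decreasing within each tier — there is
no single scalar "confounding" that rises monotonically 1→4.

The γ constants were fixed from a probit approximation of the
logistic-normal mixture before any estimator was run, targeting
threshold treatment-probability gaps of ≈0.84 (strong/low), ≈0.31
(strong/high), ≈0.12 (weak/low) and ≈0.06 (weak/high) — the last being
deliberately near zero so the weak-instrument LATE blow-up appears, as
it does in the motivating tables. γx is kept small so the binomial
(slope-free) denominator remains a good estimate of the gap *at* the
threshold over the default bandwidths.

Randomness is split into named substreams (X, U, T, ε) from one
`SeedSequence`, so the sharp variant (`T = Z` deterministically) shares
X, U and ε with its fuzzy counterpart, and identical configs are
bit-identical.

**What the generator does not emulate.** Real THIN-style records have
measured covariates, heaping and digit preference in risk scores,
missing outcome follow-up, patient (as opposed to prescriber)
non-compliance, and treatment effects that may vary with risk. Passing
tests therefore demonstrate correct recovery under the stated
generative structure — linear outcome surface, logistic adherence,
Gaussian confounder — not robustness to those real-data features.

## Simulation-study harness

`run_study` crosses confounding levels × instrument strengths × effect
sizes × bandwidths, generates R seeded cohorts per scenario
(replicate seeds derive from the master seed and scenario index, so
scenarios can run in any order or in parallel), fits the requested
estimators, and combines:

* frequentist rows by **Rubin's rules** — pooled estimate is the mean;
  total variance `W + (1 + 1/R)·B`; with R = 1 the between term is
  undefined and dropped (logged); a Rubin degrees-of-freedom t
  multiplier is available as an option, the default is 1.96;
* Bayesian rows by **averaging** the posterior means and the 95%
  credible-interval limits across replicates (means of limits, not a
  pooled posterior).

Replicate-level failures (for example an empty window side) are logged
and skipped; a scenario with more than 20% failures is flagged in the
output. The harness defaults to 100 replicates with a modest sampler
(2 chains × (500 warmup + 1000 kept)) — ample for combined estimates
whose Monte Carlo error is averaged over replicates; single-dataset
analyses use the full 4 × (2000 + 2000) default. The bandwidth sweep
defaults to {0.05, 0.15, 0.25}.

The acceptance script uses 20 replicates of n = 2000 for the recovery
check and n = 5000 for the calibration checks — sizes at which the
relevant Monte Carlo error is far below the tolerances being checked
while the whole script stays near desk-interactive speed.

## Diagnostics and binning

Exploratory bins are regular with the threshold forced onto a bin
*edge* (a straddling bin would smear the jump); bins are [left, right)
with the top edge closed, empty bins are reported with count 0 and NaN
means, and counts always sum to n. The default bin width 0.02 on the
risk-score scale is configurable. Figure smoothers are a
nearest-neighbour local mean and purely cosmetic; every number a figure
displays comes from `bin_summaries` and is testable without graphics.

## Known limitations

* The constrained denominator prior and spline outcome models are out
  of scope by design; so are covariate-adjusted outcome regressions,
  automatic bandwidth selection, multiple thresholds and patient
  non-compliance modelling.
* The LATE posterior has no moments when the Δπ posterior puts mass
  near zero; summaries in weak-instrument scenarios are reported as
  computed and should be read qualitatively (the interval width is the
  message), together with the reported fraction of near-zero
  denominator draws.
* `summarize_posterior` is meaningful for small draw counts but 95%
  interval endpoints need a few thousand draws for two-digit stability.
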