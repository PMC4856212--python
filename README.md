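# bayesrd

Bayesian and frequentist **regression discontinuity (RD)** analysis for
prescription-threshold designs in primary care, with a synthetic
statin-cohort generator and a replicate-level simulation harness.

## The problem

Many drugs are prescribed by a guideline rule on a continuous score: in
the UK, statins are recommended when a patient's 10-year cardiovascular
risk score exceeds 20%. Near that threshold the score behaves like a
randomising device, so the jump in an outcome (LDL cholesterol, mmol/l)
at the threshold estimates a causal treatment effect — an RD design.
Because prescribers do not follow the guideline perfectly, the design is
*fuzzy*, and the threshold indicator `Z = 1{X ≥ x₀}` acts as an
instrument for actual treatment `T`.

Two estimands are fitted from local linear models within a bandwidth
`h` of the threshold:

- **ATE (sharp effect)** — the outcome jump at the threshold,
  `Δβ = β₀ₐ − β₀ᵦ`, from `y ~ Normal(β₀ₗ + β₁ₗ·(x − x₀), σ²)` fitted
  separately below (`l = b`) and above (`l = a`) with a shared σ and
  `β₀ₐ = β₀ᵦ + φ`;
- **LATE (complier effect)** — that jump rescaled by the jump in
  treatment probability, `LATE = Δβ / Δπ` with `Δπ = πₐ − πᵦ` from
  binomial counts of treated patients on each side.

The Bayesian machinery lets clinical knowledge enter through priors:

| preset | prior | reading |
|---|---|---|
| `wip` | φ ~ Normal(0, 2) | weakly informative: no effect on average |
| `sip` | φ ~ Normal(−2, 1) | trial evidence: ≈2 mmol/l LDL reduction |
| `unc` | πₗ ~ Beta(1, 1) | unconstrained treatment probabilities |
| `fdp` | logit(πₐ) ~ N(2, 1), logit(πᵦ) ~ N(−2, 1) | "flexible difference": encourages, without fixing, a gap |

(Normal priors are parameterised by mean and **variance**.) The shipped
LATE models are `late_flex = Δβ_sip / Δπ_fdp` and
`late_unct = Δβ_sip / Δπ_unc`; a frequentist OLS baseline `Δβ_freq`
with 95% confidence interval is always available.

## Worked example

```python
from bayesrd import BayesianRD, CohortConfig, FrequentistRD, PriorSpec, generate_cohort

data, truth = generate_cohort(CohortConfig(n=5720, tau=2.0, seed=1))
print(FrequentistRD(data, bandwidth=0.25).fit().summary())
res = BayesianRD(data, prior=PriorSpec.preset("sip", "fdp"), bandwidth=0.25).fit(seed=1)
print(res.summary())
```

prints (abridged):

```
Delta_beta: -1.6777  (se 0.0515)
95% CI:     (-1.7787, -1.5768)

                  mean         sd       2.5%        50%      97.5%
jump           -1.6784     0.0519    -1.7800    -1.6791    -1.5755
delta_pi        0.8386     0.0077     0.8233     0.8386     0.8535
late           -2.0016     0.0644    -2.1289    -2.0021    -1.8735
```

The cohort was generated with a true statin effect of a 2 mmol/l LDL
reduction under imperfect guideline adherence (realised Δπ = 0.842).
Both ATE estimators see only the attenuated intention-to-treat jump of
about −1.68 = −2 × Δπ; the LATE divides by the estimated treatment
probability gap and recovers −2.00 with a credible interval covering
the truth. `res.all_draws`, `res.diagnostics` (split-chain R-hat and
bulk ESS per parameter) and `res.draws_dataframe()` expose the full
posterior.

## Command-line tool

```sh
bayesrd simulate --n 5720 --tau 2 --instrument strong --seed 1 --out cohort.csv
bayesrd fit cohort.csv --threshold 0.2 --bandwidth 0.05 --bandwidth 0.25 --outdir results/
bayesrd diagnose cohort.csv --threshold 0.2 --outdir diag/
bayesrd study --replicates 100 --seed 1 --outdir study/
```

`fit` writes one summary row per bandwidth per estimator plus an
assumptions report (the A1 instrument-association test, A4 covariate
continuity checks, and a statement of which assumptions are untestable);
`diagnose` writes threshold-aligned binned summaries and the standard
three-panel discontinuity plot; `study` runs the full scenario grid
(confounding levels × instrument strengths × effect sizes × bandwidths)
with per-scenario checkpointing. Every command writes a `manifest.json`
that reproduces the run exactly.

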