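"""Synthetic statin-prescription cohorts with known ground truth.

The generator emulates a UK primary-care statin scenario: a 10-year CVD
risk score ``X`` on [0, 1] with guideline threshold 0.2, an unobserved
confounder ``U`` playing the role of HDL cholesterol (predictive of both
prescription and LDL cholesterol), prescriber adherence that depends on
the threshold indicator through a logistic model, and an LDL-cholesterol
outcome in mmol/l that responds to treatment by a configured reduction
``tau``.

Generative scheme, per subject:

* ``X ~ Beta(2, 6)`` — right-skewed risk with appreciable mass near the
  0.2 threshold, plausible for a male 50+ primary-prevention cohort.
* ``U ~ Normal(0, 1)`` — standard-scale unobserved confounder.
* ``Z = 1{X >= x0}``.
* ``T ~ Bernoulli(logistic(g0 + gz*Z + gu*U + gx*(X - x0)))`` — the
  instrument strength is set by ``gz`` alone (strong or weak) and the
  treatment-side confounding by ``gu`` (low or high).
* ``Y = baseline + slope*(X - x0) - tau*T + lambda*U + eps`` with
  ``eps ~ Normal(0, sigma_eps^2)``; ``lambda`` is solved exactly (a
  sample-moment quadratic) so that the realised correlation between U
  and Y equals ``target_corr``.

Monotonicity holds by construction: treatment probability is a single
logistic with ``gz >= 0``, so no subject's propensity falls when Z flips
0 -> 1 (no defiers).  The threshold indicator enters the outcome only
through T (unconfoundedness of the guideline itself).

Confounding levels pair the treatment-side strength with the
outcome-side correlation: 1 = (low gu, corr 0.18), 2 = (low, 0.50),
3 = (high, 0.18), 4 = (high, 0.50).  Level 1 matches the correlation
observed between LDL and HDL cholesterol in the motivating database;
the 0.50 variants are the "adjusted" higher-confounding settings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from scipy.special import expit

from .data import RDDataset

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "CalibrationError",
    "generate_cohort",
    "generate_sharp_cohort",
    "write_cohort",
    "CONFOUNDING_LEVELS",
    "ASSIGNMENT_DEFAULTS",
]

# All numeric calibration targets of the generator live in these tables.
ASSIGNMENT_DEFAULTS = {
    "gamma0": -2.5,             # baseline log-odds of prescription below threshold
    "gamma_z": {"strong": 5.0, "weak": 1.0},   # instrument strength
    "gamma_u": {"low": 0.5, "high": 6.0},      # treatment-side confounding
    "gamma_x": 0.5,             # mild risk-score drift in prescription propensity
}
# level -> (gamma_u tier, confounder-outcome correlation)
CONFOUNDING_LEVELS = {
    1: ("low", 0.18),
    2: ("low", 0.50),
    3: ("high", 0.18),
    4: ("high", 0.50),
}
RISK_BETA_SHAPES = (2.0, 6.0)   # mode near 0.15, long right tail


class CalibrationError(RuntimeError):
    """Raised when the confounder-outcome correlation cannot be calibrated."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative knobs of the synthetic statin scenario.

    ``tau`` is the magnitude of the treatment REDUCTION in mmol/l; the
    outcome jump it induces is ``-tau``.  ``target_corr`` defaults to
    the value implied by ``confounding_level`` but may be overridden.
    """

    n: int = 5720
    tau: float = 2.0
    confounding_level: int = 1
    instrument: str = "strong"
    target_corr: float | None = None
    x0: float = 0.2
    seed: int = 0
    outcome_baseline: float = 3.5
    outcome_slope: float = 2.0
    sigma_eps: float = 0.8
    gamma0: float | None = None
    gamma_z: float | None = None
    gamma_u: float | None = None
    gamma_x: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.confounding_level not in CONFOUNDING_LEVELS:
            raise ValueError("confounding_level must be in 1..4")
        if self.instrument not in ("strong", "weak"):
            raise ValueError("instrument must be 'strong' or 'weak'")
        if not 0 < self.x0 < 1:
            raise ValueError("threshold x0 must lie in (0, 1)")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        if self.target_corr is not None and not -1 < self.target_corr < 1:
            raise ValueError("target_corr must lie in (-1, 1)")

    # -- resolved parameters ----------------------------------------------
    @property
    def resolved_target_corr(self) -> float:
        if self.target_corr is not None:
            return self.target_corr
        return CONFOUNDING_LEVELS[self.confounding_level][1]

    @property
    def assignment_coefficients(self) -> dict:
        tier = CONFOUNDING_LEVELS[self.confounding_level][0]
        return {
            "gamma0": self.gamma0 if self.gamma0 is not None
            else ASSIGNMENT_DEFAULTS["gamma0"],
            "gamma_z": self.gamma_z if self.gamma_z is not None
            else ASSIGNMENT_DEFAULTS["gamma_z"][self.instrument],
            "gamma_u": self.gamma_u if self.gamma_u is not None
            else ASSIGNMENT_DEFAULTS["gamma_u"][tier],
            "gamma_x": self.gamma_x if self.gamma_x is not None
            else ASSIGNMENT_DEFAULTS["gamma_x"],
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class CohortTruth:
    """Ground-truth ledger of one generated cohort."""

    tau: float
    lambda_: float
    realized_delta_pi: float
    realized_corr: float
    u: np.ndarray = field(repr=False)

    def to_dict(self, include_latents: bool = True) -> dict:
        d = {
            "tau": self.tau,
            "lambda": self.lambda_,
            "realized_delta_pi": self.realized_delta_pi,
            "realized_corr": self.realized_corr,
        }
        if include_latents:
            d["u"] = np.asarray(self.u).tolist()
        return d

    def to_json(self, include_latents: bool = True) -> str:
        return json.dumps(self.to_dict(include_latents), indent=2)


def _solve_lambda(u: np.ndarray, a: np.ndarray, rho: float) -> float:
    """Exact loading so that sample corr(U, A + lambda*U) = rho.

    Squaring the correlation identity gives a quadratic in lambda whose
    discriminant is non-negative by Cauchy-Schwarz; the root whose
    numerator sign matches rho is the solution of the unsquared
    equation.
    """
    su2 = float(np.var(u))
    sa2 = float(np.var(a))
    c = float(np.mean((u - u.mean()) * (a - a.mean())))
    if su2 <= 0:
        raise CalibrationError("confounder has zero variance; cannot calibrate")
    disc = su2 * sa2 - c * c
    lam = (-c + rho * np.sqrt(max(disc, 0.0) / (1.0 - rho * rho))) / su2
    return float(lam)


def generate_cohort(config: CohortConfig, sharp: bool = False):
    """Generate one cohort; returns ``(RDDataset, CohortTruth)``.

    One seed sequence per cohort is split into named substreams
    (X, U, T, eps) so adding a variable never perturbs the others;
    identical configs give bit-identical cohorts.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_x, rng_u, rng_t, rng_e = (np.random.default_rng(s) for s in streams)
    n = config.n

    x = rng_x.beta(*RISK_BETA_SHAPES, size=n)
    u = rng_u.standard_normal(n)
    z = (x >= config.x0).astype(int)
    xc = x - config.x0

    if sharp:
        t = z.copy()
    else:
        g = config.assignment_coefficients
        prob = expit(g["gamma0"] + g["gamma_z"] * z + g["gamma_u"] * u
                     + g["gamma_x"] * xc)
        t = (rng_t.uniform(size=n) < prob).astype(int)

    eps = rng_e.normal(scale=config.sigma_eps, size=n)
    base = (config.outcome_baseline + config.outcome_slope * xc
            - config.tau * t + eps)

    rho = config.resolved_target_corr
    lam = _solve_lambda(u, base, rho)
    y = base + lam * u

    if u.std() > 0 and y.std() > 0:
        realized = float(np.corrcoef(u, y)[0, 1])
    else:
        realized = 0.0
    if abs(realized - rho) > 0.05:
        raise CalibrationError(
            f"confounder-outcome correlation calibration failed: "
            f"achieved {realized:.4f}, target {rho:.4f}"
        )

    if z.any() and (1 - z).any():
        delta_pi = float(t[z == 1].mean() - t[z == 0].mean())
    else:
        delta_pi = float("nan")

    data = RDDataset(x=x, t=t, y=y, x0=config.x0, ids=np.arange(n))
    truth = CohortTruth(tau=config.tau, lambda_=lam,
                        realized_delta_pi=delta_pi, realized_corr=realized, u=u)
    return data, truth


def generate_sharp_cohort(config: CohortConfig):
    """Perfect-adherence (sharp design) cohort: ``t == z`` for every record."""
    return generate_cohort(config, sharp=True)


def write_cohort(data: RDDataset, truth: CohortTruth, csv_path, truth_path=None,
                 include_latents: bool = True) -> None:
    """Write the standard input CSV (id, x, t, y) plus a truth sidecar JSON."""
    data.to_dataframe().to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(truth.to_json(include_latents))
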