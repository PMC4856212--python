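"""Prior menus for the Bayesian RD models.

Two decisions drive a fuzzy RD fit: the prior on the outcome jump at the
threshold (the ATE numerator) and the prior on the treatment
probabilities either side of the threshold (the LATE denominator).

Numerator presets (prior on the jump parameter phi):

``wip``
    Weakly informative, phi ~ Normal(0, 2): on average no effect, but the
    variance is large enough for the data to overwhelm the null.
``sip``
    Strongly informative, phi ~ Normal(-2, 1): encodes the trial evidence
    that statins reduce LDL cholesterol by about 2 mmol/l.

Denominator presets (priors on pi_a, pi_b):

``unc``
    Unconstrained, pi_l ~ Beta(1, 1) independently on each side.
``fdp``
    Flexible difference prior, logit(pi_a) ~ Normal(2, 1) and
    logit(pi_b) ~ Normal(-2, 1): treatment below the threshold is a
    priori mostly below 0.5 and above the threshold mostly above it,
    encouraging (without fixing) a gap between the two.

All Normal priors are parameterised by mean and VARIANCE, matching the
Normal(m, s^2) notation of the model definitions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = ["PriorSpec", "NUMERATOR_PRESETS", "DENOMINATOR_PRESETS"]

# preset -> (phi_mean, phi_var)
NUMERATOR_PRESETS = {"wip": (0.0, 2.0), "sip": (-2.0, 1.0)}
# preset -> dict of hyperparameters
DENOMINATOR_PRESETS = {
    "unc": dict(beta_a1=1.0, beta_a2=1.0, beta_b1=1.0, beta_b2=1.0),
    "fdp": dict(la_mean=2.0, la_var=1.0, lb_mean=-2.0, lb_var=1.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Full hyperparameter set for the numerator and denominator models.

    The intercept/slope defaults (``m0=3.5``, ``s0sq=4``, flat slopes)
    are implementation defaults chosen so that prior-plausible LDL
    cholesterol levels span roughly 1-7 mmol/l over the observed risk
    range; they are not sharp substantive claims.
    """

    numerator_preset: str = "sip"
    phi_mean: float | None = None
    phi_var: float | None = None
    m0: float = 3.5
    s0sq: float = 4.0
    m1b: float = 0.0
    s1bsq: float = 100.0
    m1a: float = 0.0
    s1asq: float = 100.0
    sigma_upper: float = 5.0

    denominator_preset: str = "fdp"
    beta_a1: float = 1.0
    beta_a2: float = 1.0
    beta_b1: float = 1.0
    beta_b2: float = 1.0
    la_mean: float = 2.0
    la_var: float = 1.0
    lb_mean: float = -2.0
    lb_var: float = 1.0

    def __post_init__(self):
        if self.numerator_preset not in ("wip", "sip", "custom"):
            raise ValueError(
                f"unknown numerator preset '{self.numerator_preset}'; "
                "valid presets: wip, sip, custom"
            )
        if self.denominator_preset not in ("unc", "fdp", "custom"):
            raise ValueError(
                f"unknown denominator preset '{self.denominator_preset}'; "
                "valid presets: unc, fdp, custom"
            )
        if self.numerator_preset != "custom":
            mean, var = NUMERATOR_PRESETS[self.numerator_preset]
            object.__setattr__(self, "phi_mean", mean)
            object.__setattr__(self, "phi_var", var)
        else:
            if self.phi_mean is None or self.phi_var is None:
                raise ValueError("custom numerator preset requires phi_mean and phi_var")
        for name in ("phi_var", "s0sq", "s1bsq", "s1asq", "la_var", "lb_var"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.sigma_upper > 0:
            raise ValueError("sigma_upper must be positive")
        for name in ("beta_a1", "beta_a2", "beta_b1", "beta_b2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Beta shape {name} must be positive")

    # -- constructors -----------------------------------------------------
    @classmethod
    def preset(cls, numerator: str = "sip", denominator: str = "fdp", **overrides) -> "PriorSpec":
        return cls(numerator_preset=numerator, denominator_preset=denominator, **overrides)

    def with_numerator(self, preset: str, **kw) -> "PriorSpec":
        return replace(self, numerator_preset=preset, **kw)

    def with_denominator(self, preset: str, **kw) -> "PriorSpec":
        return replace(self, denominator_preset=preset, **kw)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PriorSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PriorSpec":
        return cls.from_dict(json.loads(text))
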