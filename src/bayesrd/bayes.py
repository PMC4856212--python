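"""Bayesian RD estimation: outcome-jump (ATE) and treatment-probability
(LATE denominator) models and their composition into the LATE.

The estimand structure mirrors the instrumental-variable reading of the
fuzzy design.  The outcome model is a two-segment local linear
regression in the centred score whose intercept jump ``phi`` at the
threshold is the ATE, Delta_beta = beta0_above - beta0_below.  The
treatment model is a pair of binomials for the number treated on each
side, whose probability gap Delta_pi = pi_a - pi_b is the denominator.
The LATE is the per-draw ratio phi / Delta_pi: the two likelihoods share
no parameters, so the posteriors are fitted independently and paired
draw by draw.

Use the :class:`BayesianRD` model class for the full workflow, or the
lower-level functions (:func:`fit_numerator`, :func:`fit_denominator`,
:func:`compose_late`) for the pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RDDataset
from .priors import PriorSpec
from .sampling import (
    SamplerSettings,
    as_seed_sequence,
    convergence_diagnostics,
    gibbs_linear_jump,
    log_beta_prior,
    log_logit_normal_prior,
    sample_binomial_probability,
)

__all__ = [
    "PosteriorResult",
    "BayesianRD",
    "BayesianRDResults",
    "fit_numerator",
    "fit_denominator",
    "compose_late",
    "summarize_posterior",
]

QUANTILES = (0.025, 0.5, 0.975)
DEFAULT_DELTA_PI_FLOOR = 0.01


def summarize_posterior(draws) -> pd.DataFrame:
    """Posterior summary table: mean, sd, 2.5% / 50% / 97.5% quantiles.

    ``draws`` is either a mapping name -> array of draws or a single
    array.  Quantiles use linear interpolation (numpy's default), so the
    summaries are exact deterministic functions of the draws.
    """
    if not isinstance(draws, dict):
        draws = {"value": draws}
    rows = {}
    for name, arr in draws.items():
        flat = np.asarray(arr, dtype=float).ravel()
        if flat.size == 0:
            raise ValueError(f"no draws for '{name}'")
        q = np.quantile(flat, QUANTILES, method="linear")
        rows[name] = {
            "mean": flat.mean(),
            "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
            "2.5%": q[0],
            "50%": q[1],
            "97.5%": q[2],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PosteriorResult:
    """Joint posterior draws plus summaries for one fitted model block.

    Attributes
    ----------
    draws : dict[str, ndarray]
        Per-parameter arrays of shape (chains, draws).
    provenance : dict
        Prior, sampler settings, bandwidth and data sizes of the fit.
    """

    draws: dict
    provenance: dict = field(default_factory=dict)
    small_denominator_fraction: float | None = None
    _summaries: pd.DataFrame | None = field(default=None, repr=False)
    _diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return int(np.asarray(first).size)

    @property
    def summaries(self) -> pd.DataFrame:
        if self._summaries is None:
            self._summaries = summarize_posterior(self.draws)
        return self._summaries

    @property
    def diagnostics(self) -> pd.DataFrame:
        if self._diagnostics is None:
            self._diagnostics = convergence_diagnostics(self.draws)
        return self._diagnostics

    def mean(self, name: str) -> float:
        return float(np.asarray(self.draws[name]).mean())

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        flat = np.asarray(self.draws[name]).ravel()
        return tuple(np.quantile(flat, [a, 1.0 - a], method="linear"))

    def draws_dataframe(self) -> pd.DataFrame:
        """One row per retained draw, one column per quantity."""
        cols = {}
        for name, arr in self.draws.items():
            a = np.asarray(arr)
            cols[name] = a.ravel()
        df = pd.DataFrame(cols)
        first = np.asarray(next(iter(self.draws.values())))
        chains, per_chain = first.shape
        df.insert(0, "chain", np.repeat(np.arange(chains), per_chain))
        df.insert(1, "draw", np.tile(np.arange(per_chain), chains))
        return df

    def summary(self) -> str:
        table = self.summaries.join(self.diagnostics, how="left")
        return table.to_string(float_format=lambda v: f"{v:10.4f}")


def fit_numerator(
    data: RDDataset, prior: PriorSpec, settings: SamplerSettings | None = None
) -> PosteriorResult:
    """Fit the Bayesian outcome-jump model on (bandwidth-filtered) data.

    Returns posterior draws of ``beta0_below, slope_below, jump,
    slope_above, sigma`` and the derived ``beta0_above = beta0_below +
    jump`` (an exact draw-by-draw identity).  Convergence diagnostics
    are computed eagerly; non-convergence raises a warning, never an
    error.
    """
    settings = settings or SamplerSettings()
    draws = gibbs_linear_jump(data.y, data.xc, data.z, prior, settings)
    draws["beta0_above"] = draws["beta0_below"] + draws["jump"]
    result = PosteriorResult(
        draws=draws,
        provenance={
            "model": "numerator",
            "prior": prior.to_dict(),
            "settings": settings.to_dict(),
            "n_below": data.n_below,
            "n_above": data.n_above,
        },
    )
    result.diagnostics  # computed now so convergence warnings fire at fit time
    return result


def fit_denominator(
    data: RDDataset, prior: PriorSpec, settings: SamplerSettings | None = None
) -> PosteriorResult:
    """Fit the treatment-probability model on (bandwidth-filtered) data.

    The number treated on each side is binomial with probability pi_l.
    Under the ``unc`` preset the prior is Beta on each side (posterior
    available in closed form, which the sampler must reproduce); under
    ``fdp`` the prior is logit-normal.  ``delta_pi = pi_a - pi_b`` is
    derived per draw.
    """
    settings = settings or SamplerSettings()
    data.require_both_sides()
    z = data.z
    s_a = int(data.t[z == 1].sum())
    s_b = int(data.t[z == 0].sum())
    n_a, n_b = data.n_above, data.n_below

    if prior.denominator_preset == "unc":
        lp_a = lambda p: log_beta_prior(p, prior.beta_a1, prior.beta_a2)
        lp_b = lambda p: log_beta_prior(p, prior.beta_b1, prior.beta_b2)
    else:  # fdp or custom logit-normal
        lp_a = lambda p: log_logit_normal_prior(p, prior.la_mean, prior.la_var)
        lp_b = lambda p: log_logit_normal_prior(p, prior.lb_mean, prior.lb_var)

    seeds = as_seed_sequence(settings.seed).spawn(2)
    pi_a = sample_binomial_probability(s_a, n_a, lp_a, settings, seed=seeds[0])
    pi_b = sample_binomial_probability(s_b, n_b, lp_b, settings, seed=seeds[1])
    draws = {"pi_above": pi_a, "pi_below": pi_b, "delta_pi": pi_a - pi_b}
    return PosteriorResult(
        draws=draws,
        provenance={
            "model": "denominator",
            "prior": prior.to_dict(),
            "settings": settings.to_dict(),
            "n_below": n_b, "n_above": n_a,
            "treated_below": s_b, "treated_above": s_a,
        },
    )


def compose_late(
    numerator: PosteriorResult,
    denominator: PosteriorResult,
    floor: float = DEFAULT_DELTA_PI_FLOOR,
) -> PosteriorResult:
    """Per-draw LATE = jump / delta_pi, pairing draw i with draw i.

    The two posteriors are independent (the likelihoods share no
    parameters), so index-wise pairing is a valid joint sample.  Draws
    with |delta_pi| below ``floor`` are counted and reported in
    ``small_denominator_fraction`` but never removed: a near-zero
    denominator is the weak-instrument pathology itself and must be
    visible in the summaries, not sanitised away.
    """
    phi = np.asarray(numerator.draws["jump"])
    dpi = np.asarray(denominator.draws["delta_pi"])
    if phi.shape != dpi.shape:
        raise ValueError(
            f"mismatched draw shapes: numerator {phi.shape} vs denominator {dpi.shape}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        late = phi / dpi
    frac_small = float(np.mean(np.abs(dpi) < floor))
    return PosteriorResult(
        draws={"jump": phi, "delta_pi": dpi, "late": late},
        provenance={
            "model": "late",
            "floor": floor,
            "numerator": numerator.provenance,
            "denominator": denominator.provenance,
        },
        small_denominator_fraction=frac_small,
    )


class BayesianRD:
    """Bayesian regression discontinuity model for one dataset.

    Parameters
    ----------
    data : RDDataset
        Patient-level records with the threshold.
    prior : PriorSpec, optional
        Numerator and denominator priors; defaults to the sip/fdp
        combination (the "flexible" LATE model).
    bandwidth : float, optional
        Half-width of the local window around the threshold.  If given,
        the model is fit on records with ``|x - x0| <= bandwidth``;
        otherwise on all records.
    late_floor : float
        Threshold below which |delta_pi| draws are counted as near-zero.

    Examples
    --------
    >>> model = BayesianRD(dataset, prior=PriorSpec.preset("sip", "fdp"),
    ...                    bandwidth=0.25)
    >>> res = model.fit(seed=1)
    >>> res.late_mean, res.late_ci
    """

    def __init__(self, data: RDDataset, prior: PriorSpec | None = None,
                 bandwidth: float | None = None,
                 late_floor: float = DEFAULT_DELTA_PI_FLOOR):
        self.prior = prior or PriorSpec()
        self.bandwidth = bandwidth
        self.late_floor = late_floor
        self.data = data.filter_bandwidth(bandwidth) if bandwidth is not None else data
        self.data.require_both_sides()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x0: float, **kw) -> "BayesianRD":
        model_kw = {k: kw.pop(k) for k in ("prior", "bandwidth", "late_floor") if k in kw}
        return cls(RDDataset.from_dataframe(df, x0=x0, **kw), **model_kw)

    def fit(self, settings: SamplerSettings | None = None, *,
            chains: int = 4, warmup: int = 2000, draws: int = 2000,
            seed: int | None = None) -> "BayesianRDResults":
        if settings is None:
            settings = SamplerSettings(chains=chains, warmup=warmup,
                                       draws=draws, seed=seed)
        seeds = as_seed_sequence(settings.seed).spawn(2)
        num = fit_numerator(self.data, self.prior, settings.replaced(seed=seeds[0]))
        den = fit_denominator(self.data, self.prior, settings.replaced(seed=seeds[1]))
        late = compose_late(num, den, floor=self.late_floor)
        return BayesianRDResults(self, num, den, late, settings)


class BayesianRDResults:
    """Results of a :class:`BayesianRD` fit.

    Carries the three posterior blocks (numerator, denominator, LATE),
    convenience point estimates with 95% credible intervals, convergence
    diagnostics and a printable summary table.
    """

    def __init__(self, model: BayesianRD, numerator: PosteriorResult,
                 denominator: PosteriorResult, late: PosteriorResult,
                 settings: SamplerSettings):
        self.model = model
        self.numerator = numerator
        self.denominator = denominator
        self.late = late
        self.settings = settings

    # -- headline estimands ------------------------------------------------
    @property
    def ate_mean(self) -> float:
        return self.numerator.mean("jump")

    @property
    def ate_ci(self) -> tuple[float, float]:
        return self.numerator.ci("jump")

    @property
    def delta_pi_mean(self) -> float:
        return self.denominator.mean("delta_pi")

    @property
    def late_mean(self) -> float:
        return self.late.mean("late")

    @property
    def late_ci(self) -> tuple[float, float]:
        return self.late.ci("late")

    @property
    def small_denominator_fraction(self) -> float:
        return self.late.small_denominator_fraction

    @property
    def all_draws(self) -> dict:
        merged = dict(self.numerator.draws)
        merged.update(self.denominator.draws)
        merged["late"] = self.late.draws["late"]
        return merged

    @property
    def summaries(self) -> pd.DataFrame:
        return summarize_posterior(self.all_draws)

    @property
    def diagnostics(self) -> pd.DataFrame:
        return pd.concat([self.numerator.diagnostics, self.denominator.diagnostics])

    def draws_dataframe(self) -> pd.DataFrame:
        num = self.numerator.draws_dataframe()
        den = self.denominator.draws_dataframe().drop(columns=["chain", "draw"])
        late = self.late.draws_dataframe()[["late"]]
        return pd.concat([num, den, late], axis=1)

    def summary(self) -> str:
        prior = self.model.prior
        head = [
            "Bayesian regression discontinuity fit",
            "=" * 54,
            f"numerator prior:   {prior.numerator_preset}  "
            f"(phi ~ Normal({prior.phi_mean:g}, {prior.phi_var:g}))",
            f"denominator prior: {prior.denominator_preset}",
            f"bandwidth:         {self.model.bandwidth}",
            f"records:           {self.model.data.n_below} below / "
            f"{self.model.data.n_above} above",
            f"sampler:           {self.settings.chains} chains x "
            f"{self.settings.draws} draws (+{self.settings.warmup} warmup)",
            f"|delta_pi| < {self.model.late_floor:g} in "
            f"{100 * self.small_denominator_fraction:.2f}% of draws",
            "",
        ]
        return "\n".join(head) + self.summaries.to_string(
            float_format=lambda v: f"{v:10.4f}"
        )
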