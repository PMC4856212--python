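"""Frequentist ATE baseline for the RD design.

Fits the two-segment local linear regression by ordinary least squares,
one fit per side of the threshold, and reports the intercept difference
Delta_beta_freq = beta0_above - beta0_below with a normal-approximation
95% confidence interval.  This is the comparator column of the
simulation-study tables; no frequentist LATE is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data import EmptySideError, RDDataset

__all__ = ["FreqEstimate", "ols_ate", "FrequentistRD", "Z95"]

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class FreqEstimate:
    """OLS estimate of the outcome jump at the threshold."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_below: int
    n_above: int

    def __post_init__(self):
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must contain the estimate")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def _side_fit(xc: np.ndarray, y: np.ndarray, side: str) -> tuple[float, float]:
    """Intercept and its variance from one side's OLS line.

    A saturated side (exactly as many records as parameters) has no
    residual degrees of freedom; its variance contribution is taken as
    zero, which also makes exact-fit data report se = 0.
    """
    n = len(y)
    if n < 2:
        raise EmptySideError(side, f"need >= 2 records {side} the threshold, got {n}")
    if np.ptp(xc) == 0.0:
        raise ValueError(f"degenerate design: all assignment scores equal on the '{side}' side")
    X = sm.add_constant(xc)
    fit = sm.OLS(y, X).fit()
    if n == 2:
        var0 = 0.0
    else:
        var0 = float(fit.cov_params()[0, 0])
        if not np.isfinite(var0):
            var0 = 0.0
    return float(fit.params[0]), var0


def ols_ate(data: RDDataset) -> FreqEstimate:
    """Frequentist Delta_beta on (bandwidth-filtered) data.

    Fits ``y = beta0l + beta1l * (x - x0)`` separately by OLS below and
    above the threshold.  The estimate is the intercept difference; its
    standard error combines the two independent fits,
    ``sqrt(se_a^2 + se_b^2)``; the 95% CI uses the standard normal
    multiplier.
    """
    data.require_both_sides()
    z = data.z
    xc = data.xc
    b0_below, var_below = _side_fit(xc[z == 0], data.y[z == 0], "below")
    b0_above, var_above = _side_fit(xc[z == 1], data.y[z == 1], "above")
    est = b0_above - b0_below
    se = float(np.sqrt(var_below + var_above))
    return FreqEstimate(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        n_below=data.n_below,
        n_above=data.n_above,
    )


class FrequentistRD:
    """Model-object wrapper around :func:`ols_ate`.

    Mirrors :class:`bayesrd.bayes.BayesianRD`: construct with a dataset
    and optional bandwidth, call :meth:`fit` for a
    :class:`FrequentistRDResults`.
    """

    def __init__(self, data: RDDataset, bandwidth: float | None = None):
        self.bandwidth = bandwidth
        self.data = data.filter_bandwidth(bandwidth) if bandwidth is not None else data

    def fit(self) -> "FrequentistRDResults":
        return FrequentistRDResults(self, ols_ate(self.data))


class FrequentistRDResults:
    def __init__(self, model: FrequentistRD, estimate: FreqEstimate):
        self.model = model
        self.est = estimate

    @property
    def estimate(self) -> float:
        return self.est.estimate

    @property
    def se(self) -> float:
        return self.est.se

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.est.ci_low, self.est.ci_high)

    def summary(self) -> str:
        e = self.est
        return "\n".join([
            "Frequentist regression discontinuity fit (OLS)",
            "=" * 48,
            f"bandwidth:  {self.model.bandwidth}",
            f"records:    {e.n_below} below / {e.n_above} above",
            f"Delta_beta: {e.estimate:.4f}  (se {e.se:.4f})",
            f"95% CI:     ({e.ci_low:.4f}, {e.ci_high:.4f})",
        ])
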