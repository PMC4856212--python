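"""Replicate-level simulation-study harness.

Runs every requested estimator over R independently generated cohorts
per scenario and combines the replicate results into one table row per
(scenario, estimator):

* frequentist estimates are pooled with Rubin's rules (mean of
  estimates; within + between variance; normal-quantile interval);
* Bayesian estimates are combined by averaging the posterior means and
  the 95% credible-interval limits across replicates.

Scenario replicate seeds are derived deterministically from the master
seed and the scenario index, so scenarios can be run in any order, in
parallel, or resumed, with identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import compose_late, fit_denominator, fit_numerator
from .cohort import CohortConfig, generate_cohort
from .data import filter_bandwidth
from .freq import Z95, ols_ate
from .priors import PriorSpec
from .sampling import SamplerSettings

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "StudyConfig",
    "StudyResult",
    "CombinedEstimate",
    "rubin_combine",
    "bayes_combine",
    "run_study",
    "ALL_ESTIMATORS",
]

ALL_ESTIMATORS = ("freq", "wip", "sip", "late_unct", "late_flex")
BAYES_ESTIMATORS = {"wip", "sip", "late_unct", "late_flex"}
FAILURE_FLAG_FRACTION = 0.2


@dataclass(frozen=True)
class Scenario:
    confounding_level: int = 1
    instrument: str = "strong"
    tau: float = 2.0
    bandwidth: float = 0.25

    def label(self) -> str:
        return (f"level{self.confounding_level}-{self.instrument}"
                f"-tau{self.tau:g}-h{self.bandwidth:g}")


@dataclass(frozen=True)
class StudyConfig:
    """Scenario grid and execution settings for one simulation study."""

    scenarios: tuple = ()
    replicates: int = 100
    n: int = 5720
    estimators: tuple = ALL_ESTIMATORS
    master_seed: int = 0
    sampler: SamplerSettings = field(
        default_factory=lambda: SamplerSettings(chains=2, warmup=500, draws=1000)
    )
    late_floor: float = 0.01

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        for s in self.scenarios:
            if not s.bandwidth > 0:
                raise ValueError("bandwidths must be positive")
        unknown = set(self.estimators) - set(ALL_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")

    @classmethod
    def grid(cls, confounding_levels=(1, 3), instruments=("strong", "weak"),
             taus=(2.0,), bandwidths=(0.05, 0.15, 0.25), **kw) -> "StudyConfig":
        scen = tuple(
            Scenario(level, inst, tau, h)
            for inst in instruments
            for level in confounding_levels
            for tau in taus
            for h in bandwidths
        )
        return cls(scenarios=scen, **kw)


@dataclass(frozen=True)
class CombinedEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    variance: float | None = None
    method: str = "rubin"


def rubin_combine(estimates, variances, df_adjust: bool = False) -> CombinedEstimate:
    """Pool replicate estimates with Rubin's rules.

    Pooled estimate is the mean; total variance is W + (1 + 1/R) B with
    W the mean within-replicate variance and B the between-replicate
    variance of the estimates.  With R = 1 the between term is undefined
    and is dropped (total = W), which is logged as a caveat.  The
    interval uses the normal 1.96 multiplier by default; ``df_adjust``
    switches to the Rubin degrees-of-freedom t multiplier.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    if (var < 0).any():
        raise ValueError("variances must be non-negative")
    r = len(est)
    pooled = float(est.mean())
    w = float(var.mean())
    if r == 1:
        logger.warning("Rubin's rules with a single replicate: "
                       "between-replicate variance undefined, using within only")
        total = w
        mult = Z95
    else:
        b = float(est.var(ddof=1))
        total = w + (1.0 + 1.0 / r) * b
        mult = Z95
        if df_adjust and b > 0:
            nu = (r - 1) * (1.0 + w / ((1.0 + 1.0 / r) * b)) ** 2
            mult = float(stats.t.ppf(0.975, nu))
    half = mult * float(np.sqrt(total))
    return CombinedEstimate(pooled, pooled - half, pooled + half, total, "rubin")


def bayes_combine(summaries) -> CombinedEstimate:
    """Average posterior means and 95% interval limits across replicates.

    ``summaries`` is a sequence of (mean, lower, upper) triples, one per
    replicate.
    """
    arr = np.asarray(list(summaries), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("each replicate summary must be a (mean, lower, upper) triple")
    mean, lo, hi = arr.mean(axis=0)
    return CombinedEstimate(float(mean), float(lo), float(hi), None, "bayes-average")


@dataclass
class StudyResult:
    """Combined table plus per-replicate raw estimates."""

    table: pd.DataFrame
    raw: pd.DataFrame
    config: StudyConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        cols = ["confounding_level", "instrument", "tau", "bandwidth",
                "estimator", "estimate", "ci_low", "ci_high", "flagged"]
        df = self.table[cols].copy()
        for c in ("estimate", "ci_low", "ci_high"):
            df[c] = df[c].map(lambda v: f"{v:.2f}")
        return df.to_markdown(index=False)


def _replicate_seed(master_seed: int, scenario_index: int, rep: int, salt: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(scenario_index),
                                 int(rep), int(salt)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _fit_replicate(window, estimators, sampler: SamplerSettings,
                   fit_seed: int, late_floor: float) -> dict:
    """All requested estimator summaries on one bandwidth-filtered cohort."""
    out = {}
    if "freq" in estimators:
        fe = ols_ate(window)
        out["freq"] = {"estimate": fe.estimate, "variance": fe.se ** 2,
                       "ci_low": fe.ci_low, "ci_high": fe.ci_high}

    seeds = np.random.SeedSequence(fit_seed).spawn(4)
    need_sip = bool({"sip", "late_unct", "late_flex"} & set(estimators))
    num_sip = None
    if need_sip:
        num_sip = fit_numerator(window, PriorSpec.preset("sip"),
                                sampler.replaced(seed=seeds[0]))
        if "sip" in estimators:
            lo, hi = num_sip.ci("jump")
            out["sip"] = {"estimate": num_sip.mean("jump"), "ci_low": lo, "ci_high": hi}
    if "wip" in estimators:
        num_wip = fit_numerator(window, PriorSpec.preset("wip"),
                                sampler.replaced(seed=seeds[1]))
        lo, hi = num_wip.ci("jump")
        out["wip"] = {"estimate": num_wip.mean("jump"), "ci_low": lo, "ci_high": hi}
    for name, preset, seed in (("late_unct", "unc", seeds[2]),
                               ("late_flex", "fdp", seeds[3])):
        if name in estimators:
            den = fit_denominator(window, PriorSpec.preset("sip", preset),
                                  sampler.replaced(seed=seed))
            late = compose_late(num_sip, den, floor=late_floor)
            lo, hi = late.ci("late")
            out[name] = {"estimate": late.mean("late"), "ci_low": lo, "ci_high": hi,
                         "frac_small_denominator": late.small_denominator_fraction}
    return out


def _run_scenario(config: StudyConfig, idx: int, scenario: Scenario) -> pd.DataFrame:
    rows = []
    for rep in range(config.replicates):
        cohort_seed = _replicate_seed(config.master_seed, idx, rep, 0)
        fit_seed = _replicate_seed(config.master_seed, idx, rep, 1)
        cc = CohortConfig(n=config.n, tau=scenario.tau,
                          confounding_level=scenario.confounding_level,
                          instrument=scenario.instrument, seed=cohort_seed)
        try:
            data, _truth = generate_cohort(cc)
            window = filter_bandwidth(data, scenario.bandwidth)
            fits = _fit_replicate(window, config.estimators, config.sampler,
                                  fit_seed, config.late_floor)
        except Exception as exc:  # logged, never aborts the study
            logger.warning("scenario %s replicate %d failed: %s",
                           scenario.label(), rep, exc)
            rows.append({"replicate": rep, "estimator": "__failure__",
                         "error": str(exc)})
            continue
        for name, vals in fits.items():
            rows.append({"replicate": rep, "estimator": name, **vals})
    return pd.DataFrame(rows)


def _combine_scenario(scenario: Scenario, raw: pd.DataFrame,
                      config: StudyConfig) -> list[dict]:
    n_failed = int((raw["estimator"] == "__failure__").sum()) if len(raw) else 0
    flagged = n_failed > FAILURE_FLAG_FRACTION * config.replicates
    out = []
    for est in config.estimators:
        sub = raw[raw["estimator"] == est]
        if len(sub) == 0:
            continue
        if est == "freq":
            comb = rubin_combine(sub["estimate"].to_numpy(),
                                 sub["variance"].to_numpy())
        else:
            comb = bayes_combine(
                sub[["estimate", "ci_low", "ci_high"]].to_numpy()
            )
        out.append({
            "confounding_level": scenario.confounding_level,
            "instrument": scenario.instrument,
            "tau": scenario.tau,
            "bandwidth": scenario.bandwidth,
            "estimator": est,
            "estimate": comb.estimate,
            "ci_low": comb.ci_low,
            "ci_high": comb.ci_high,
            "method": comb.method,
            "n_replicates": int(sub["replicate"].nunique()),
            "n_failures": n_failed,
            "flagged": flagged,
        })
    return out


def run_study(config: StudyConfig, checkpoint_dir=None) -> StudyResult:
    """Run the full scenario grid; resumable per scenario.

    With ``checkpoint_dir`` set, each scenario's per-replicate results
    are written to ``<dir>/<label>.csv`` on completion and reloaded on a
    rerun, so an interrupted study resumes where it stopped and yields
    the same final table.
    """
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    table_rows, raw_frames = [], []
    for idx, scenario in enumerate(config.scenarios):
        ckpt = (checkpoint_dir / f"scenario-{idx}-{scenario.label()}.csv"
                if checkpoint_dir is not None else None)
        if ckpt is not None and ckpt.exists():
            raw = pd.read_csv(ckpt)
            logger.info("scenario %s loaded from checkpoint", scenario.label())
        else:
            raw = _run_scenario(config, idx, scenario)
            if ckpt is not None:
                raw.to_csv(ckpt, index=False)
        raw = raw.assign(scenario=scenario.label())
        raw_frames.append(raw)
        table_rows.extend(_combine_scenario(scenario, raw, config))

    table = pd.DataFrame(table_rows)
    raw_all = pd.concat(raw_frames, ignore_index=True) if raw_frames else pd.DataFrame()
    return StudyResult(table=table, raw=raw_all, config=config)
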