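"""Exploratory plots and assumption checks for the RD design.

The standard exploratory display bins the assignment score into regular
intervals aligned so the threshold is a bin *edge* (a straddling bin
would smear the jump) and plots the per-bin mean outcome and raw treated
proportion: visible jumps at the threshold support the design.

Of the identifying assumptions, only two have testable pieces:

* A1 (instrument relevance): the association between the threshold
  indicator Z and treatment T is directly estimable
  (:func:`test_instrument_association`).
* A4 (continuity): partly testable on *observed* covariates — a
  discontinuity of a covariate at the threshold undermines the design
  (:func:`covariate_continuity`).

Guideline independence (A2), unconfoundedness of the indicator (A3) and
monotonicity / no defiers (A5) involve unobserved quantities and cannot
be tested from the data; the assumptions report states this rather than
inventing tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import EmptySideError, RDDataset
from .freq import Z95

__all__ = [
    "BinnedSummary",
    "InstrumentAssociation",
    "CovariateContinuity",
    "bin_summaries",
    "test_instrument_association",
    "covariate_continuity",
    "assumptions_report",
    "plot_discontinuity",
    "UNTESTABLE_NOTE",
]

UNTESTABLE_NOTE = (
    "A2 (guideline independence), A3 (unconfoundedness of the threshold "
    "indicator) and A5 (monotonicity / no defiers) involve unobserved "
    "confounders or counterfactual prescription strategies and cannot be "
    "tested from the observed data; they must be argued substantively."
)


def threshold_aligned_edges(x: np.ndarray, x0: float, width: float) -> np.ndarray:
    """Regular bin edges of the given width with ``x0`` on an edge."""
    if not width > 0:
        raise ValueError("bin width must be positive")
    xmin, xmax = float(x.min()), float(x.max())
    if width > xmax - xmin:
        warnings.warn("bin width exceeds the data range; a single bin per side "
                      "at most will be populated", stacklevel=2)
    k_lo = int(np.ceil((x0 - xmin) / width)) if xmin < x0 else 0
    k_hi = int(np.ceil((xmax - x0) / width)) if xmax > x0 else 0
    k_lo, k_hi = max(k_lo, 1), max(k_hi, 1)
    return x0 + width * np.arange(-k_lo, k_hi + 1)


@dataclass
class BinnedSummary:
    """Per-bin counts, mean outcome and treated proportion."""

    edges: np.ndarray
    midpoints: np.ndarray
    counts: np.ndarray
    mean_outcome: np.ndarray
    treated_proportion: np.ndarray
    x0: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.edges[:-1],
            "bin_right": self.edges[1:],
            "midpoint": self.midpoints,
            "count": self.counts,
            "mean_outcome": self.mean_outcome,
            "treated_proportion": self.treated_proportion,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def side_means(self) -> tuple[float, float]:
        """Mean treated proportion over populated bins (below, above) the threshold."""
        below = self.midpoints < self.x0
        ok = self.counts > 0
        return (
            float(np.nanmean(self.treated_proportion[below & ok])),
            float(np.nanmean(self.treated_proportion[~below & ok])),
        )


def _bin_means(x: np.ndarray, values: np.ndarray, edges: np.ndarray):
    """Counts and per-bin means; bins are [left, right), last bin closed."""
    idx = np.digitize(x, edges[1:-1], right=False)
    nbins = len(edges) - 1
    counts = np.bincount(idx, minlength=nbins).astype(int)
    sums = np.bincount(idx, weights=values, minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return counts, means


def bin_summaries(data: RDDataset, bin_width: float = 0.02) -> BinnedSummary:
    """Regular threshold-aligned bins with per-bin mean outcome and treated share.

    Empty bins are reported with count 0 and NaN means; counts sum to n.
    """
    edges = threshold_aligned_edges(data.x, data.x0, bin_width)
    counts, mean_y = _bin_means(data.x, data.y, edges)
    _, mean_t = _bin_means(data.x, data.t.astype(float), edges)
    return BinnedSummary(
        edges=edges,
        midpoints=(edges[:-1] + edges[1:]) / 2.0,
        counts=counts,
        mean_outcome=mean_y,
        treated_proportion=mean_t,
        x0=data.x0,
    )


@dataclass
class InstrumentAssociation:
    """A1 check: association between the threshold indicator and treatment."""

    table: pd.DataFrame          # 2x2 counts, rows z, columns t
    proportion_difference: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    weak_instrument: bool
    floor: float

    def __str__(self) -> str:
        flag = "WEAK" if self.weak_instrument else "ok"
        return (
            "A1 instrument relevance (Z vs T)\n"
            f"{self.table.to_string()}\n"
            f"treated-proportion difference: {self.proportion_difference:.3f} "
            f"(95% CI {self.ci_low:.3f}, {self.ci_high:.3f})\n"
            f"chi-square: {self.chi2:.2f} (p = {self.p_value:.3g})\n"
            f"strength (floor {self.floor:g}): {flag}"
        )


def test_instrument_association(data: RDDataset, floor: float = 0.1) -> InstrumentAssociation:
    """Estimate the Z-T association: 2x2 table, proportion difference, chi-square.

    Flags a weak instrument when the treated-proportion difference falls
    below ``floor`` (default 0.1).
    """
    data.require_both_sides()
    z, t = data.z, data.t
    counts = np.array([
        [int(((z == zi) & (t == ti)).sum()) for ti in (0, 1)] for zi in (0, 1)
    ])
    table = pd.DataFrame(counts, index=pd.Index([0, 1], name="z"),
                         columns=pd.Index([0, 1], name="t"))
    n0, n1 = counts[0].sum(), counts[1].sum()
    p0, p1 = counts[0, 1] / n0, counts[1, 1] / n1
    diff = p1 - p0
    se = float(np.sqrt(p0 * (1 - p0) / n0 + p1 * (1 - p1) / n1))
    if (counts.sum(axis=0) > 0).all():
        chi2, pval = stats.chi2_contingency(counts, correction=False)[:2]
    else:  # degenerate column (e.g. t identical to z): association is total
        chi2, pval = float("inf"), 0.0
    return InstrumentAssociation(
        table=table,
        proportion_difference=float(diff),
        ci_low=float(diff - Z95 * se),
        ci_high=float(diff + Z95 * se),
        chi2=float(chi2),
        p_value=float(pval),
        weak_instrument=bool(diff < floor),
        floor=floor,
    )


@dataclass
class CovariateContinuity:
    """A4 check on one observed covariate: binned means across the threshold."""

    covariate: str
    bins: pd.DataFrame
    adjacent_difference: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:
        return (
            f"A4 continuity check for '{self.covariate}': adjacent-bin "
            f"difference at the threshold {self.adjacent_difference:.4f} "
            f"(95% CI {self.ci_low:.4f}, {self.ci_high:.4f})"
        )


def covariate_continuity(data: RDDataset, covariate: str,
                         bin_width: float = 0.02) -> CovariateContinuity:
    """Binned means of an observed covariate across the threshold.

    Reports the difference between the two bins adjacent to the
    threshold with a normal-approximation 95% CI; a clear discontinuity
    calls assumption A4 into question.
    """
    if covariate not in data.covariates:
        raise ValueError(f"covariate column '{covariate}' not present in dataset")
    values = np.asarray(data.covariates[covariate], dtype=float)
    edges = threshold_aligned_edges(data.x, data.x0, bin_width)
    counts, means = _bin_means(data.x, values, edges)
    sq_counts, sq_means = _bin_means(data.x, values ** 2, edges)
    with np.errstate(invalid="ignore"):
        variances = np.maximum(sq_means - means ** 2, 0.0)
    mid = (edges[:-1] + edges[1:]) / 2.0
    bins = pd.DataFrame({"midpoint": mid, "count": counts, "mean": means})

    below_idx = np.flatnonzero((mid < data.x0) & (counts > 0))
    above_idx = np.flatnonzero((mid > data.x0) & (counts > 0))
    if len(below_idx) == 0:
        raise EmptySideError("below")
    if len(above_idx) == 0:
        raise EmptySideError("above")
    i, j = below_idx[-1], above_idx[0]
    diff = means[j] - means[i]
    se = float(np.sqrt(variances[i] / counts[i] + variances[j] / counts[j]))
    return CovariateContinuity(
        covariate=covariate,
        bins=bins,
        adjacent_difference=float(diff),
        ci_low=float(diff - Z95 * se),
        ci_high=float(diff + Z95 * se),
    )


def assumptions_report(data: RDDataset, covariates: list[str] | None = None,
                       bin_width: float = 0.02, weak_floor: float = 0.1) -> str:
    """Plain-text report of the testable assumption checks.

    Covers A1 (always) and A4 for each requested covariate; states
    explicitly that A2, A3 and A5 are untestable.
    """
    parts = ["RD design assumptions report", "=" * 60]
    parts.append(str(test_instrument_association(data, floor=weak_floor)))
    for cov in covariates or list(data.covariates):
        parts.append("")
        parts.append(str(covariate_continuity(data, cov, bin_width=bin_width)))
    parts += ["", UNTESTABLE_NOTE]
    return "\n".join(parts)


def _local_mean(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                frac: float = 0.3) -> np.ndarray:
    """Nearest-neighbour local mean smoother (cosmetic overlay only)."""
    k = max(int(frac * len(x)), 2)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty_like(grid)
    for m, g in enumerate(grid):
        idx = np.argsort(np.abs(xs - g))[:k]
        out[m] = ys[idx].mean()
    return out


def plot_discontinuity(data: RDDataset, bin_width: float = 0.02,
                       smoother: bool = True, axes=None):
    """Three-panel display: raw scatter, binned mean outcome, binned treated share.

    All numbers shown are produced by :func:`bin_summaries`; the figure
    is a pure rendering.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    summary = bin_summaries(data, bin_width)
    if axes is None:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    else:
        fig = axes[0].figure

    ax = axes[0]
    ax.scatter(data.x, data.y, s=4, alpha=0.3)
    ax.set_xlabel("assignment score")
    ax.set_ylabel("outcome")
    ax.set_title("raw data")

    ok = summary.counts > 0
    specs = [("mean_outcome", "binned mean outcome"),
             ("treated_proportion", "binned treated proportion")]
    for ax, (attr, title) in zip(axes[1:], specs):
        vals = getattr(summary, attr)
        ax.plot(summary.midpoints[ok], vals[ok], "o", ms=4)
        if smoother and ok.sum() >= 4:
            for side in (summary.midpoints < data.x0, summary.midpoints > data.x0):
                sel = ok & side
                if sel.sum() >= 2:
                    grid = np.linspace(summary.midpoints[sel].min(),
                                       summary.midpoints[sel].max(), 50)
                    ax.plot(grid, _local_mean(summary.midpoints[sel], vals[sel], grid),
                            "-", lw=1, color="grey")
        ax.set_xlabel("risk-score bin midpoint")
        ax.set_title(title)
    for ax in axes:
        ax.axvline(data.x0, ls="--", color="k", lw=0.8)
    fig.tight_layout()
    return fig
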