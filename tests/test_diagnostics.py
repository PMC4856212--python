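import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bayesrd import (
    CohortConfig,
    RDDataset,
    assumptions_report,
    bin_summaries,
    covariate_continuity,
    generate_cohort,
    generate_sharp_cohort,
    test_instrument_association as instrument_association,
)
from bayesrd.diagnostics import UNTESTABLE_NOTE, threshold_aligned_edges


def _dataset(x, t=None, y=None, x0=0.2, **covs):
    x = np.asarray(x, dtype=float)
    t = (x >= x0).astype(int) if t is None else np.asarray(t)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return RDDataset(x=x, t=t, y=y, x0=x0, covariates=covs)


def test_bin_summaries_example():
    d = _dataset([0.11, 0.19, 0.21, 0.29], y=[1.0, 2.0, 3.0, 4.0])
    s = bin_summaries(d, 0.1)
    populated = s.counts > 0
    np.testing.assert_array_equal(s.counts[populated], [2, 2])
    np.testing.assert_allclose(s.midpoints[populated], [0.15, 0.25])
    np.testing.assert_allclose(s.mean_outcome[populated], [1.5, 3.5])
    assert s.counts.sum() == d.n
    # threshold sits exactly on an edge
    assert np.any(np.isclose(s.edges, 0.2))


def test_sharp_cohort_bin_proportions():
    data, _ = generate_sharp_cohort(CohortConfig(n=2000, seed=1))
    s = bin_summaries(data, 0.02)
    ok = s.counts > 0
    below = ok & (s.midpoints < 0.2)
    above = ok & (s.midpoints > 0.2)
    assert np.all(s.treated_proportion[below] == 0.0)
    assert np.all(s.treated_proportion[above] == 1.0)


@given(st.floats(0.005, 0.3))
def test_threshold_never_interior_to_a_bin(width):
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 0.6, 200)
    edges = threshold_aligned_edges(x, 0.2, width)
    # 0.2 coincides with an edge up to floating error
    assert np.min(np.abs(edges - 0.2)) < 1e-9
    assert edges[0] <= x.min() and edges[-1] >= x.max() - 1e-12


def test_binned_jump_estimates_delta_pi():
    data, truth = generate_cohort(CohortConfig(n=20000, seed=6))
    s = bin_summaries(data.filter_bandwidth(0.1), 0.02)
    below, above = s.side_means()
    assert (above - below) == pytest.approx(truth.realized_delta_pi, abs=0.05)


def test_single_bin_warning():
    d = _dataset([0.19, 0.21])
    with pytest.warns(UserWarning, match="single bin"):
        bin_summaries(d, 0.5)


def test_instrument_association_examples():
    # deterministic adherence: difference exactly 1
    d = _dataset(np.linspace(0.05, 0.35, 40))
    rep = instrument_association(d)
    assert rep.proportion_difference == pytest.approx(1.0)
    assert not rep.weak_instrument

    # 5/50 treated below, 40/50 above -> difference 0.70
    t = np.r_[np.ones(5), np.zeros(45), np.ones(40), np.zeros(10)].astype(int)
    x = np.r_[np.full(50, 0.1), np.full(50, 0.3)]
    rep2 = instrument_association(_dataset(x, t=t))
    assert rep2.proportion_difference == pytest.approx(0.70)
    assert rep2.ci_low < 0.70 < rep2.ci_high
    assert rep2.chi2 > 0


def test_instrument_independence_detected():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 0.4, 4000)
    t = rng.integers(0, 2, 4000)
    rep = instrument_association(_dataset(x, t=t))
    assert rep.ci_low <= 0.0 <= rep.ci_high
    assert rep.weak_instrument


def test_covariate_continuity_cases():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 0.4, 5000)
    const = np.full(5000, 2.5)
    indep = rng.normal(size=5000)
    d = _dataset(x, c_const=const, c_indep=indep, c_self=x)

    r_const = covariate_continuity(d, "c_const")
    assert r_const.adjacent_difference == 0.0

    r_indep = covariate_continuity(d, "c_indep")
    assert r_indep.ci_low <= 0.0 <= r_indep.ci_high

    # the covariate equal to x jumps by about one bin width across the edge
    r_self = covariate_continuity(d, "c_self", bin_width=0.02)
    assert r_self.adjacent_difference == pytest.approx(0.02, abs=0.005)

    with pytest.raises(ValueError, match="not present"):
        covariate_continuity(d, "missing")


def test_assumptions_report_mentions_untestable(tmp_path):
    data, _ = generate_cohort(CohortConfig(n=500, seed=2))
    text = assumptions_report(data)
    assert "A1" in text
    assert UNTESTABLE_NOTE in text


def test_plot_is_pure_rendering(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from bayesrd import plot_discontinuity

    data, _ = generate_cohort(CohortConfig(n=500, seed=2))
    fig = plot_discontinuity(data, 0.05)
    fig.savefig(tmp_path / "fig.png")
    assert (tmp_path / "fig.png").stat().st_size > 0
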