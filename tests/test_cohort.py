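import io

import numpy as np
import pytest

from bayesrd import CohortConfig, generate_cohort, generate_sharp_cohort, ols_ate
from bayesrd.cohort import ASSIGNMENT_DEFAULTS, CONFOUNDING_LEVELS


def test_risk_scores_and_sizes():
    cfg = CohortConfig(n=3000, seed=0)
    data, truth = generate_cohort(cfg)
    assert data.n == 3000
    assert data.x.min() >= 0 and data.x.max() <= 1
    assert len(truth.u) == 3000


@pytest.mark.parametrize("target", [0.18, 0.5])
def test_confounder_outcome_correlation_calibrated(target):
    _, truth = generate_cohort(CohortConfig(n=5000, seed=2, target_corr=target))
    assert truth.realized_corr == pytest.approx(target, abs=0.05)


def test_null_effect_covered_by_freq_ci():
    """With tau = 0 the OLS jump's own 95% CI covers 0 (majority over seeds)."""
    covered = 0
    for seed in (1, 2, 3):
        data, _ = generate_cohort(CohortConfig(n=5000, tau=0.0, seed=seed))
        est = ols_ate(data.filter_bandwidth(0.25))
        covered += est.ci_low <= 0.0 <= est.ci_high
    assert covered >= 2


def test_instrument_strength_calibration_targets():
    _, strong = generate_cohort(CohortConfig(n=5000, seed=3, instrument="strong"))
    _, weak = generate_cohort(CohortConfig(n=5000, seed=3, instrument="weak"))
    assert strong.realized_delta_pi >= 0.6
    assert weak.realized_delta_pi <= 0.35


def test_sharp_cohort_has_perfect_adherence():
    data, truth = generate_sharp_cohort(CohortConfig(n=1000, seed=4))
    np.testing.assert_array_equal(data.t, data.z)
    assert truth.realized_delta_pi == 1.0


def test_seed_determinism_bit_identical():
    cfg = CohortConfig(n=500, seed=11)
    d1, t1 = generate_cohort(cfg)
    d2, t2 = generate_cohort(cfg)
    buf1, buf2 = io.StringIO(), io.StringIO()
    d1.to_dataframe().to_csv(buf1, index=False)
    d2.to_dataframe().to_csv(buf2, index=False)
    assert buf1.getvalue() == buf2.getvalue()
    assert t1.lambda_ == t2.lambda_


def test_substreams_isolated_across_adherence():
    """Sharp and fuzzy cohorts from one seed share X; the threshold indicator
    reaches the outcome only through treatment (and the recalibrated
    confounder loading)."""
    cfg = CohortConfig(n=2000, seed=8)
    fuzzy, tf = generate_cohort(cfg)
    sharp, ts = generate_sharp_cohort(cfg)
    np.testing.assert_array_equal(fuzzy.x, sharp.x)
    np.testing.assert_array_equal(tf.u, ts.u)
    # removing each cohort's treatment and confounder terms leaves the same
    # z-free residual surface: no direct Z -> Y path exists
    resid_f = fuzzy.y + cfg.tau * fuzzy.t - tf.lambda_ * tf.u
    resid_s = sharp.y + cfg.tau * sharp.t - ts.lambda_ * ts.u
    np.testing.assert_allclose(resid_f, resid_s, atol=1e-10)


def test_monotonicity_by_construction():
    """Treatment propensity never decreases when Z flips 0 -> 1."""
    for strength, gz in ASSIGNMENT_DEFAULTS["gamma_z"].items():
        assert gz >= 0, strength
    cfg = CohortConfig(n=100, seed=0, instrument="weak", confounding_level=4)
    g = cfg.assignment_coefficients
    rng = np.random.default_rng(0)
    u = rng.standard_normal(100)
    xc = rng.uniform(-0.2, 0.2, 100)
    from scipy.special import expit

    p0 = expit(g["gamma0"] + g["gamma_u"] * u + g["gamma_x"] * xc)
    p1 = expit(g["gamma0"] + g["gamma_z"] + g["gamma_u"] * u + g["gamma_x"] * xc)
    assert np.all(p1 >= p0)


def test_confounding_ordering():
    """U-T association rises with the gamma_u tier; U-Y association rises
    with the target correlation within each tier."""
    def cohort(level):
        return generate_cohort(CohortConfig(n=8000, seed=5, confounding_level=level))

    assoc_ut, corr_uy = {}, {}
    for level in (1, 2, 3, 4):
        data, truth = cohort(level)
        assoc_ut[level] = abs(np.corrcoef(truth.u, data.t)[0, 1])
        corr_uy[level] = truth.realized_corr
    assert assoc_ut[3] > assoc_ut[1]
    assert assoc_ut[4] > assoc_ut[2]
    assert corr_uy[2] > corr_uy[1]
    assert corr_uy[4] > corr_uy[3]


def test_config_validation_and_serialisation():
    with pytest.raises(ValueError, match="n must be"):
        CohortConfig(n=0)
    with pytest.raises(ValueError, match="confounding_level"):
        CohortConfig(confounding_level=5)
    with pytest.raises(ValueError, match="instrument"):
        CohortConfig(instrument="medium")
    cfg = CohortConfig(n=10, tau=0.5, confounding_level=2, seed=3)
    assert CohortConfig.from_yaml(cfg.to_yaml()) == cfg
    assert CONFOUNDING_LEVELS[cfg.confounding_level] == ("low", 0.50)
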