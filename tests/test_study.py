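import numpy as np
import pandas as pd
import pytest

from bayesrd import Scenario, StudyConfig, bayes_combine, rubin_combine, run_study
from bayesrd.sampling import SamplerSettings

TINY = SamplerSettings(chains=2, warmup=200, draws=400)


def test_rubin_hand_arithmetic():
    """W = 0.25, B = 1, total = 0.25 + (4/3) = 1.58333..., pooled -2."""
    comb = rubin_combine([-2.0, -1.0, -3.0], [0.25, 0.25, 0.25])
    assert comb.estimate == pytest.approx(-2.0)
    assert comb.variance == pytest.approx(0.25 + (1 + 1 / 3) * 1.0)
    assert comb.variance == pytest.approx(1.5833333333333333)


def test_rubin_single_replicate_uses_within_only(caplog):
    with caplog.at_level("WARNING"):
        comb = rubin_combine([-1.5], [0.04])
    assert comb.estimate == -1.5
    assert comb.variance == pytest.approx(0.04)
    assert "single replicate" in caplog.text


def test_rubin_identical_estimates():
    comb = rubin_combine([3.0, 3.0, 3.0, 3.0], [0.5, 0.5, 0.5, 0.5])
    assert comb.estimate == 3.0
    assert comb.variance == pytest.approx(0.5)


def test_rubin_validation():
    with pytest.raises(ValueError, match="equal-length"):
        rubin_combine([1.0, 2.0], [0.1])
    with pytest.raises(ValueError, match="non-negative"):
        rubin_combine([1.0], [-0.1])


def test_bayes_combine_examples():
    one = bayes_combine([(-2.0, -2.5, -1.5)])
    assert (one.estimate, one.ci_low, one.ci_high) == (-2.0, -2.5, -1.5)
    two = bayes_combine([(-2.0, -2.4, -1.6), (-2.2, -2.6, -1.8)])
    assert two.estimate == pytest.approx(-2.1)
    assert two.ci_low <= two.estimate <= two.ci_high
    with pytest.raises(ValueError, match="triple"):
        bayes_combine([(-2.0, -2.5)])


def test_study_config_validation():
    with pytest.raises(ValueError, match="scenario"):
        StudyConfig(scenarios=(), replicates=2)
    with pytest.raises(ValueError, match="unknown estimators"):
        StudyConfig(scenarios=(Scenario(),), estimators=("freq", "magic"))
    grid = StudyConfig.grid(bandwidths=(0.05, 0.25), replicates=1)
    assert len(grid.scenarios) == 8  # 2 instruments x 2 levels x 1 tau x 2 h


def test_single_replicate_row_equals_fit_summaries():
    cfg = StudyConfig(scenarios=(Scenario(1, "strong", 2.0, 0.25),),
                      replicates=1, n=800, estimators=("freq", "sip"),
                      master_seed=3, sampler=TINY)
    res = run_study(cfg)
    raw_sip = res.raw[res.raw.estimator == "sip"].iloc[0]
    row_sip = res.table[res.table.estimator == "sip"].iloc[0]
    assert row_sip["estimate"] == raw_sip["estimate"]
    assert row_sip["ci_low"] == raw_sip["ci_low"]
    assert (res.table["n_replicates"] == 1).all()


def test_study_determinism_and_checkpoint_resume(tmp_path):
    cfg = StudyConfig(scenarios=(Scenario(1, "strong", 2.0, 0.25),),
                      replicates=2, n=600, estimators=("freq", "late_flex"),
                      master_seed=9, sampler=TINY)
    a = run_study(cfg, checkpoint_dir=tmp_path / "ck")
    b = run_study(cfg)  # fresh run, no checkpoints
    c = run_study(cfg, checkpoint_dir=tmp_path / "ck")  # resumed from disk
    pd.testing.assert_frame_equal(a.table, b.table)
    pd.testing.assert_frame_equal(
        a.table, c.table, check_exact=False, rtol=1e-12
    )


def test_ate_attenuation_under_fuzziness():
    """Where 0 < delta_pi < 1 the combined |ATE| cannot exceed the combined |LATE|."""
    cfg = StudyConfig(scenarios=(Scenario(1, "strong", 2.0, 0.25),),
                      replicates=4, n=1500, estimators=("sip", "late_flex"),
                      master_seed=5, sampler=TINY)
    table = run_study(cfg).table.set_index("estimator")
    assert abs(table.loc["sip", "estimate"]) <= abs(table.loc["late_flex", "estimate"])


def test_freq_bias_toward_zero_with_rising_confounding():
    """With a weak instrument the frequentist jump attenuates toward 0 as the
    treatment-side confounding level rises."""
    cfg = StudyConfig(
        scenarios=(Scenario(1, "weak", 2.0, 0.25), Scenario(3, "weak", 2.0, 0.25)),
        replicates=8, n=4000, estimators=("freq",), master_seed=17, sampler=TINY,
    )
    table = run_study(cfg).table.set_index("confounding_level")
    assert abs(table.loc[3, "estimate"]) < abs(table.loc[1, "estimate"])


def test_markdown_and_csv_outputs(tmp_path):
    cfg = StudyConfig(scenarios=(Scenario(1, "strong", 2.0, 0.25),),
                      replicates=1, n=600, estimators=("freq",), master_seed=1)
    res = run_study(cfg)
    res.to_csv(tmp_path / "study.csv")
    loaded = pd.read_csv(tmp_path / "study.csv")
    assert {"estimator", "estimate", "ci_low", "ci_high"} <= set(loaded.columns)
    assert "estimate" in res.to_markdown()
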