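import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bayesrd import (
    RDDataset,
    assign_threshold_indicator,
    center_scores,
    filter_bandwidth,
    read_dataset,
)
from bayesrd.data import EmptySideError

finite_floats = st.floats(-10, 10, allow_nan=False)


@pytest.mark.parametrize(
    "x, x0, expected",
    [
        ([0.19, 0.20, 0.21], 0.20, [0, 1, 1]),
        ([0.5], 0.5, [1]),  # boundary is inclusive above
        ([0.0, 0.05, 0.35], 0.2, [0, 0, 1]),
    ],
)
def test_threshold_indicator(x, x0, expected):
    np.testing.assert_array_equal(assign_threshold_indicator(x, x0), expected)


def test_threshold_indicator_rejects_nonfinite_with_index():
    with pytest.raises(ValueError, match="index 1"):
        assign_threshold_indicator([0.1, np.nan, 0.3], 0.2)


@pytest.mark.parametrize(
    "x, x0, expected",
    [
        ([0.15, 0.20, 0.30], 0.20, [-0.05, 0.0, 0.10]),
        ([0.2], 0.2, [0.0]),
    ],
)
def test_center_scores(x, x0, expected):
    np.testing.assert_allclose(center_scores(x, x0), expected, atol=1e-15)


@given(st.lists(finite_floats, min_size=1, max_size=30), finite_floats)
def test_center_uncenter_roundtrip(x, x0):
    # exact up to one rounding step of the subtraction at magnitude |x0|
    np.testing.assert_allclose(
        center_scores(x, x0) + x0,
        np.asarray(x, dtype=float),
        rtol=0,
        atol=4 * np.finfo(float).eps * max(1.0, abs(x0)),
    )


def _dataset(x, x0=0.2):
    x = np.asarray(x, dtype=float)
    z = (x >= x0).astype(int)
    return RDDataset(x=x, t=z, y=np.zeros_like(x), x0=x0)


def test_filter_bandwidth_examples():
    d = _dataset([0.10, 0.16, 0.24, 0.50])
    kept = filter_bandwidth(d, 0.05)
    np.testing.assert_allclose(sorted(kept.x), [0.16, 0.24])
    assert kept.n_below == 1 and kept.n_above == 1
    # boundary of the window is closed on both sides
    d2 = _dataset([0.15, 0.25])
    assert filter_bandwidth(d2, 0.05).n == 2
    # a bandwidth covering the whole range retains everything
    assert filter_bandwidth(d, 1.0).n == d.n


def test_filter_bandwidth_errors():
    d = _dataset([0.1, 0.3])
    with pytest.raises(ValueError, match="positive"):
        filter_bandwidth(d, 0.0)
    with pytest.raises(EmptySideError, match="above"):
        filter_bandwidth(_dataset([0.15, 0.16, 0.9]), 0.06)
    with pytest.raises(EmptySideError, match="below"):
        filter_bandwidth(_dataset([0.02, 0.21, 0.22]), 0.05)


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=50),
    st.floats(0.01, 0.5),
    st.floats(0.01, 0.5),
)
def test_filter_properties(x, h1, h2):
    """Filtering is idempotent, monotone in h, and commutes with the indicator."""
    d = _dataset(x)
    h_small, h_big = min(h1, h2), max(h1, h2)

    def keep(h):
        try:
            return filter_bandwidth(d, h)
        except EmptySideError:
            return None

    small, big = keep(h_small), keep(h_big)
    if small is not None:
        again = filter_bandwidth(small, h_small)
        np.testing.assert_array_equal(again.x, small.x)
        # indicator computed before or after filtering agrees
        mask = np.abs(d.x - d.x0) <= h_small
        np.testing.assert_array_equal(small.z, d.z[mask])
        if big is not None:
            assert set(np.round(small.x, 12)) <= set(np.round(big.x, 12))


def test_dataset_validation():
    with pytest.raises(ValueError, match="0/1"):
        RDDataset(x=[0.1, 0.3], t=[0, 2], y=[1.0, 2.0], x0=0.2)
    with pytest.raises(ValueError, match="equal length"):
        RDDataset(x=[0.1, 0.3], t=[0], y=[1.0, 2.0], x0=0.2)
    with pytest.raises(ValueError, match="at least one"):
        RDDataset(x=[], t=[], y=[], x0=0.2)


def test_from_dataframe_drops_missing_with_log(caplog):
    df = pd.DataFrame({
        "x": [0.1, np.nan, 0.3, 0.4],
        "t": [0, 0, 1, 1],
        "y": [1.0, 2.0, np.nan, 3.0],
    })
    with caplog.at_level("WARNING"):
        d = RDDataset.from_dataframe(df, x0=0.2)
    assert d.n == 2
    assert "dropped 2" in caplog.text


def test_read_dataset_roundtrip(tmp_path):
    path = tmp_path / "cohort.csv"
    df = pd.DataFrame({"id": [1, 2, 3], "x": [0.1, 0.2, 0.3],
                       "t": [0, 1, 1], "y": [3.1, 2.0, 1.2],
                       "hdl": [1.2, 1.0, 0.9]})
    df.to_csv(path, index=False)
    d = read_dataset(path, x0=0.2, covariate_cols=["hdl"])
    assert d.n == 3
    np.testing.assert_array_equal(d.z, [0, 1, 1])
    assert "hdl" in d.covariates
    with pytest.raises(ValueError, match="required column"):
        read_dataset(path, x0=0.2, y_col="missing")
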