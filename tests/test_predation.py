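import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goldmim.predation import (GutScreenTable, adjust_screen_frequencies,
                               availability_chisq, capture_probability,
                               classify_guild, killing_value, killing_values,
                               smooth_regression)


def small_screen():
    idx = pd.Index(["p1", "p2", "p3"], name="predator_id")
    freq = pd.DataFrame({"m1": [0.0, 0.1, 0.2], "m2": [0.0, 0.0, 0.0]},
                        index=idx)
    return GutScreenTable(
        frequencies=freq,
        guild=pd.Series(["visual", "ant_eating", "non_visual"], index=idx),
        n_screened=pd.Series([50, 40, 30], index=idx),
        size_limited=pd.Series([False, False, True], index=idx))


def test_capture_probability_exact_points():
    assert capture_probability(1.99 / 2.11) == 0.5
    assert capture_probability(0.0) == pytest.approx(1 / (1 + math.exp(-1.99)),
                                                     abs=1e-15)
    r = np.linspace(0, 3, 50)
    p = capture_probability(r)
    assert np.all(np.diff(p) < 0)  # strictly decreasing
    with pytest.raises(ValueError):
        capture_probability(-0.1)


def test_killing_value_hand_examples():
    assert killing_value([0.0, 0.0, 0.0]) == 0.0
    assert killing_value([0.5]) == pytest.approx(math.log(2.0))
    assert killing_value([0.5], base="log10") == pytest.approx(math.log10(2.0))
    with pytest.raises(ValueError):
        killing_value([1.0])
    with pytest.raises(ValueError):
        killing_value([0.5], base="log2")


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 0.95), min_size=1, max_size=8),
       st.lists(st.floats(0, 0.95), min_size=1, max_size=8))
def test_killing_value_additive_and_monotone(fa, fb):
    k_joint = killing_value(fa + fb)
    assert k_joint == pytest.approx(killing_value(fa) + killing_value(fb),
                                    abs=1e-12)
    bumped = list(fa)
    bumped[0] = min(bumped[0] + 0.01, 0.99)
    assert killing_value(bumped) >= killing_value(fa)


def test_killing_values_table_matches_columnwise():
    gs = small_screen()
    res = killing_values(gs)
    for m in gs.mimics:
        assert res.k[m] == pytest.approx(
            killing_value(gs.frequencies[m].to_numpy()))
    assert np.allclose(res.contributions.sum(axis=0), res.k)
    assert res.k["m2"] == 0.0


def test_adjustment_touches_only_flagged_predators():
    gs = small_screen()
    sizes = pd.Series({"p3": 10.0})
    msize = pd.Series({"m1": 5.0, "m2": 8.0})
    out = adjust_screen_frequencies(gs, sizes, msize)
    pd.testing.assert_frame_equal(out.frequencies.loc[["p1", "p2"]],
                                  gs.frequencies.loc[["p1", "p2"]])
    expect = gs.frequencies.loc["p3", "m1"] * capture_probability(5.0 / 10.0)
    assert out.frequencies.loc["p3", "m1"] == pytest.approx(expect)
    with pytest.raises(ValueError):
        adjust_screen_frequencies(gs, pd.Series(dtype=float), msize)


def test_classify_guild_boundary():
    assert classify_guild(0.10) == "euryphagous"
    assert classify_guild(0.101) == "ant_eating"
    with pytest.raises(ValueError):
        classify_guild(1.5)


def test_availability_chisq_hand_example():
    # obs (8,2) vs equal availability -> expected (5,5), X^2 = 9/5+9/5 = 3.6
    stat, df, p = availability_chisq([8, 2], [50, 50])
    assert stat == pytest.approx(3.6)
    assert df == 1
    from scipy import stats as ss
    assert p == pytest.approx(ss.chi2.sf(3.6, 1))
    with pytest.raises(ValueError):
        availability_chisq([1, 1], [0, 0])
    with pytest.raises(ValueError):
        availability_chisq([1, 1], [1, 0])


def test_percent_table_round_trip():
    df = pd.DataFrame({
        "predator_id": ["a", "b"], "family": ["F", "G"],
        "guild": ["visual", "non_visual"], "size_limited": [0, 1],
        "N": [10, 20], "m1": [5.0, 0.0], "m2": [0.0, 2.5]})
    gs = GutScreenTable.from_percent_table(df)
    assert gs.frequencies.loc["a", "m1"] == pytest.approx(0.05)
    assert gs.size_limited["b"]
    assert list(gs.mimics) == ["m1", "m2"]


def test_gut_screen_validation():
    idx = pd.Index(["p"], name="predator_id")
    with pytest.raises(ValueError):
        GutScreenTable(frequencies=pd.DataFrame({"m": [1.2]}, index=idx),
                       guild=pd.Series(["visual"], index=idx),
                       n_screened=pd.Series([10], index=idx),
                       size_limited=pd.Series([False], index=idx))
    with pytest.raises(ValueError):
        GutScreenTable(frequencies=pd.DataFrame({"m": [0.2]}, index=idx),
                       guild=pd.Series(["psychic"], index=idx),
                       n_screened=pd.Series([10], index=idx),
                       size_limited=pd.Series([False], index=idx))


def test_smooth_regression_noise_free_monotone(rng):
    u = np.sort(rng.uniform(0, 7, 13))
    K = np.exp(0.2 + 0.3 * u)  # exactly log-linear
    fit = smooth_regression(u, K)
    assert np.allclose(fit.fitted, np.log(K), atol=1e-6)
    assert fit.p_value < 1e-6
    assert np.all(np.diff(fit.fitted[np.argsort(u)]) > -1e-9)


def test_smooth_regression_zero_k_epsilon(rng):
    u = np.linspace(0, 7, 13)
    K = np.concatenate([[0.0], rng.uniform(0.1, 1.0, 12)])
    fit = smooth_regression(u, K)
    assert fit.epsilon == pytest.approx(0.5 * K[K > 0].min())
    with pytest.raises(ValueError):
        smooth_regression(u[:4], K[:4])
    with pytest.raises(ValueError):
        smooth_regression(np.zeros(13), K)
    with pytest.raises(ValueError):
        smooth_regression(u, -K)
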