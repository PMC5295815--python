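import numpy as np
import pandas as pd
import pytest

from goldmim.unpalatability import (CORE_TRAITS, TraitTable, bartlett_test,
                                    ellipse_gland_area,
                                    fit_trait_interpolators,
                                    impute_missing_traits,
                                    unpalatability_index)


def toy_table():
    data = pd.DataFrame({
        "sting_length_mm": [1.0, 2.0, 0.0],
        "n_spines": [4.0, 0.0, 2.0],
        "total_spine_length_mm": [2.0, 0.0, 1.0],
        "mandible_size_mm": [0.5, 1.0, 0.25],
        "cuticle_thickness_mm": [0.02, 0.04, 0.02],
        "gland_area_mm2": [3.0, 1.5, 0.0],
        "communal_attack": [1.0, 0.0, 1.0],
        "gaster_length_mm": [3.0, 4.0, 2.0],
        "thorax_length_mm": [2.0, 3.0, 1.5],
    }, index=pd.Index(["x", "y", "z"], name="species_id"))
    return TraitTable(data)


def test_index_matches_hand_computation():
    res = unpalatability_index(toy_table())
    # u_x = 1/2 + 4/4 + 2/2 + 0.5/1 + 0.02/0.04 + 3/3 + 1/1 = 5.0
    assert res.u["x"] == pytest.approx(0.5 + 1 + 1 + 0.5 + 0.5 + 1 + 1)
    assert res.u["y"] == pytest.approx(1 + 0 + 0 + 1 + 1 + 0.5 + 0)
    assert (res.weight == 1.0).all()


def test_index_invariant_to_trait_rescaling():
    tt = toy_table()
    res1 = unpalatability_index(tt)
    scaled = tt.data.copy()
    scaled["gland_area_mm2"] *= 37.5  # unit change must not matter
    res2 = unpalatability_index(TraitTable(scaled))
    assert np.allclose(res1.u, res2.u)


def test_all_zero_trait_column_excluded():
    tt = toy_table()
    data = tt.data.copy()
    data["n_spines"] = 0.0
    res = unpalatability_index(TraitTable(data))
    assert "n_spines" not in res.trait_maxima.index
    # the zero column contributes nothing rather than 0/0
    assert np.isfinite(res.u).all()


def test_negative_trait_rejected():
    data = toy_table().data.copy()
    data.loc["x", "n_spines"] = -1.0
    with pytest.raises(ValueError):
        TraitTable(data)


def test_interpolators_match_polyfit_oracle(rng):
    n = 20
    gaster = rng.uniform(1, 5, n)
    thorax = rng.uniform(1, 4, n)
    data = pd.DataFrame({
        "gland_area_mm2": 0.8 * gaster + rng.normal(0, 0.1, n),
        "sting_length_mm": 0.3 * gaster + rng.normal(0, 0.05, n),
        "cuticle_thickness_mm": 0.01 * thorax + rng.normal(0, 0.001, n),
        "n_spines": np.full(n, 2.0),
        "total_spine_length_mm": np.full(n, 1.0),
        "mandible_size_mm": np.full(n, 0.5),
        "communal_attack": np.zeros(n),
        "gaster_length_mm": gaster,
        "thorax_length_mm": thorax,
    }, index=pd.Index([f"s{i}" for i in range(n)], name="species_id"))
    data["gland_area_mm2"] = data["gland_area_mm2"].clip(lower=0)
    models = fit_trait_interpolators(TraitTable(data))
    slope, intercept = np.polyfit(gaster, data["gland_area_mm2"], 1)
    assert models["gland_area_mm2"].slope == pytest.approx(slope, rel=1e-10)
    assert models["gland_area_mm2"].intercept == pytest.approx(intercept,
                                                               rel=1e-8)
    # predictions are floored at zero
    assert models["gland_area_mm2"].predict([-1000.0]) == pytest.approx(0.0)


def test_imputation_never_touches_observed_cells(rng):
    n = 15
    gaster = rng.uniform(1, 5, n)
    data = pd.DataFrame({
        "gland_area_mm2": 0.8 * gaster + rng.normal(0, 0.1, n),
        "sting_length_mm": rng.uniform(0.5, 1.5, n),
        "n_spines": rng.integers(0, 6, n).astype(float),
        "total_spine_length_mm": rng.uniform(0, 3, n),
        "mandible_size_mm": rng.uniform(0.2, 1.0, n),
        "cuticle_thickness_mm": rng.uniform(0.01, 0.05, n),
        "communal_attack": rng.integers(0, 2, n).astype(float),
        "gaster_length_mm": gaster,
        "thorax_length_mm": rng.uniform(1, 4, n),
    }, index=pd.Index([f"s{i}" for i in range(n)], name="species_id"))
    data["gland_area_mm2"] = data["gland_area_mm2"].clip(lower=0)
    holes = data.copy()
    holes.loc[["s0", "s3"], "gland_area_mm2"] = np.nan
    tt = TraitTable(holes)
    models = fit_trait_interpolators(tt)
    filled = impute_missing_traits(tt, models)
    observed_idx = [f"s{i}" for i in range(n) if i not in (0, 3)]
    pd.testing.assert_frame_equal(filled.data.loc[observed_idx],
                                  holes.loc[observed_idx])
    assert filled.data["gland_area_mm2"].notna().all()
    assert not filled.observed.loc["s0", "gland_area_mm2"]
    # imputed species carry lower weight
    res = unpalatability_index(filled)
    assert res.weight["s0"] < res.weight["s1"]
    assert res.weight["s0"] == pytest.approx(6 / 7)


def test_interpolator_needs_three_complete_species():
    data = toy_table().data.copy()
    data.loc[["y", "z"], "gland_area_mm2"] = np.nan
    with pytest.raises(ValueError):
        fit_trait_interpolators(TraitTable(data))


def test_ellipse_gland_area():
    assert ellipse_gland_area(2.0, 4.0) == pytest.approx(np.pi * 1.0 * 2.0)
    assert ellipse_gland_area(0.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        ellipse_gland_area(-1.0, 1.0)


def test_bartlett_matches_textbook_formula(rng):
    groups = [rng.normal(0, s, n) for s, n in ((1.0, 8), (2.0, 10), (1.5, 7))]
    values = np.concatenate(groups)
    labels = np.repeat(["a", "b", "c"], [8, 10, 7])
    stat, df, p = bartlett_test(values, labels)
    # textbook Bartlett statistic, computed independently
    k = 3
    ns = np.array([8, 10, 7])
    vs = np.array([np.var(g, ddof=1) for g in groups])
    n_tot = ns.sum()
    sp2 = np.sum((ns - 1) * vs) / (n_tot - k)
    num = (n_tot - k) * np.log(sp2) - np.sum((ns - 1) * np.log(vs))
    den = 1 + (np.sum(1 / (ns - 1)) - 1 / (n_tot - k)) / (3 * (k - 1))
    assert stat == pytest.approx(num / den, rel=1e-10)
    assert df == 2


def test_bartlett_requirements():
    with pytest.raises(ValueError):
        bartlett_test([1.0, 2.0, 3.0], ["a", "a", "a"])
    with pytest.raises(ValueError):
        bartlett_test([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])
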