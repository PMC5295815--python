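import numpy as np
import pytest
import statsmodels.api as sm

from goldmim.phylo import (BrownianVCV, estimate_lambda_ml, gls_fit, load_tree,
                           max_feasible_lambda, pagel_transform,
                           tree_from_genus_table, vcv_from_tree)
from goldmim.simulate import SimConfig, draw_brownian_tips, simulate_tree_bm

SISTER_PAIR = "((a:0.5,b:0.5):0.5,c:1.0);"


def test_vcv_sister_pair_hand_example():
    V = vcv_from_tree(load_tree(SISTER_PAIR, is_path=False))
    idx = {t: i for i, t in enumerate(V.taxa)}
    m = V.matrix
    assert m[idx["a"], idx["a"]] == pytest.approx(1.0)
    assert m[idx["a"], idx["b"]] == pytest.approx(0.5)
    assert m[idx["a"], idx["c"]] == pytest.approx(0.0)
    assert m[idx["c"], idx["c"]] == pytest.approx(1.0)


def test_vcv_matches_mrca_depth_oracle():
    """Brute-force oracle: V[a,b] = distance from root to MRCA(a,b)."""
    import dendropy
    from dendropy.simulate import treesim
    import random
    for seed in range(4):
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=9,
            rng=random.Random(seed))
        V = vcv_from_tree(tree)
        pdm = tree.phylogenetic_distance_matrix()  # forces indexing
        labels = V.taxa
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                ta = tree.taxon_namespace.get_taxon(a)
                tb = tree.taxon_namespace.get_taxon(b)
                if i == j:
                    node = tree.find_node_for_taxon(ta)
                    expect = node.distance_from_root()
                else:
                    mrca = tree.mrca(taxa=[ta, tb])
                    expect = mrca.distance_from_root()
                assert V.matrix[i, j] == pytest.approx(expect, abs=1e-10), \
                    (seed, a, b)


def test_pagel_transform_examples():
    V = vcv_from_tree(load_tree(SISTER_PAIR, is_path=False))
    half = pagel_transform(V, 0.5)
    idx = {t: i for i, t in enumerate(V.taxa)}
    assert half.matrix[idx["a"], idx["b"]] == pytest.approx(0.25)
    assert half.matrix[idx["a"], idx["a"]] == pytest.approx(1.0)
    star = pagel_transform(V, 0.0)
    assert np.allclose(star.matrix, np.diag(np.diag(V.matrix)))
    with pytest.raises(ValueError):
        pagel_transform(V, -0.1)


def test_lambda_above_one_feasibility():
    V = vcv_from_tree(load_tree(SISTER_PAIR, is_path=False))
    lam_max = max_feasible_lambda(V)
    assert lam_max > 1.0
    # feasible bound is sharp: just above it the matrix loses PSD
    with pytest.raises(ValueError):
        pagel_transform(V, lam_max + 0.05)
    m = pagel_transform(V, lam_max).matrix
    assert np.linalg.eigvalsh(m).min() >= -1e-8


def test_star_tree_admits_any_lambda():
    star = load_tree("(a:1,b:1,c:1,d:1);", is_path=False)
    V = vcv_from_tree(star)
    # diagonal V: the Pagel transform only rescales zero off-diagonals
    assert max_feasible_lambda(V, upper=5.0) == pytest.approx(5.0)


def test_gls_identity_covariance_equals_ols(rng):
    n = 40
    x = rng.standard_normal(n)
    y = 1.0 + 2.0 * x + rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    V = BrownianVCV(matrix=np.eye(n), taxa=[f"s{i}" for i in range(n)])
    fit = gls_fit(X, y, V)
    ols = sm.OLS(y, X).fit()
    assert np.allclose(fit.coefficients, ols.params, atol=1e-10)
    assert np.allclose(fit.std_errors, ols.bse, atol=1e-10)
    assert fit.f_statistic == pytest.approx(ols.fvalue, rel=1e-10)
    assert fit.f_pvalue == pytest.approx(ols.f_pvalue, rel=1e-8)
    assert fit.log_likelihood == pytest.approx(ols.llf, rel=1e-10)


def test_gls_weights_scale_invariance(rng):
    n = 25
    tree, _, V = simulate_tree_bm(SimConfig(seed=5, n_species=n))
    x = rng.standard_normal(n)
    y = 2.0 * x + draw_brownian_tips(V, 1.0, rng)
    X = np.column_stack([np.ones(n), x])
    w = rng.uniform(0.3, 1.0, n)
    fit1 = gls_fit(X, y, V, case_weights=w)
    fit2 = gls_fit(X, y, V, case_weights=3.7 * w)
    assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-10)
    assert fit1.f_statistic == pytest.approx(fit2.f_statistic, rel=1e-10)
    with pytest.raises(ValueError):
        gls_fit(X, y, V, case_weights=np.zeros(n))


def test_gls_singular_design_raises(rng):
    n = 10
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x, x])
    V = BrownianVCV(matrix=np.eye(n), taxa=[f"s{i}" for i in range(n)])
    with pytest.raises(np.linalg.LinAlgError):
        gls_fit(X, rng.standard_normal(n), V)


def test_lambda_flat_profile_warns(rng):
    n = 12
    V = BrownianVCV(matrix=np.eye(n), taxa=[f"s{i}" for i in range(n)])
    y = rng.standard_normal(n)
    with pytest.warns(UserWarning, match="flat profile"):
        lam, fit = estimate_lambda_ml(np.ones((n, 1)), y, V)
    assert fit.lambda_warning is not None


def test_lambda_point_estimate_reasonable():
    tree, trait, V = simulate_tree_bm(SimConfig(seed=11, n_species=60))
    lam, fit = estimate_lambda_ml(np.ones((len(V), 1)),
                                  trait.loc[V.taxa].to_numpy(float), V)
    assert 0.7 <= lam <= max_feasible_lambda(V) + 1e-9
    assert fit.lam == pytest.approx(lam)


def test_tree_from_genus_table_structure():
    genus_of = {"g1_a": "G1", "g1_b": "G1", "g2_a": "G2"}
    tree = tree_from_genus_table(genus_of)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assert labels == set(genus_of)
    V = vcv_from_tree(tree)
    idx = {t: i for i, t in enumerate(V.taxa)}
    # congeners share the full genus branch; different genera share nothing
    assert V.matrix[idx["g1_a"], idx["g1_b"]] == pytest.approx(1.0)
    assert V.matrix[idx["g1_a"], idx["g2_a"]] == pytest.approx(0.0)


def test_load_tree_rejects_negative_branch():
    with pytest.raises(ValueError):
        load_tree("((a:1,b:-0.5):1,c:2);", is_path=False)
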