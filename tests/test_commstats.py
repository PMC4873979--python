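"""Ordination, model selection, permutation tests and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import biofilmflow as bf
from biofilmflow.commstats import variance_inflation_factors


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def test_hellinger_closed_forms():
    out = bf.hellinger_transform(pd.DataFrame([[25, 75]]))
    np.testing.assert_allclose(out.to_numpy()[0], [0.5, np.sqrt(0.75)],
                               atol=5e-6)
    uniform = bf.hellinger_transform(pd.DataFrame([[3, 3, 3, 3]]))
    np.testing.assert_allclose(uniform.to_numpy()[0], 0.5)
    with_zero = bf.hellinger_transform(pd.DataFrame([[0, 10]]))
    assert with_zero.iloc[0, 0] == 0.0


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=2,
                max_size=6).filter(lambda r: sum(r) > 0),
       st.integers(min_value=1, max_value=1000))
def test_hellinger_unit_rows_and_scale_invariance(row, scale):
    counts = pd.DataFrame([row], dtype=float)
    h1 = bf.hellinger_transform(counts)
    np.testing.assert_allclose((h1.to_numpy() ** 2).sum(axis=1), 1.0)
    h2 = bf.hellinger_transform(counts * scale)  # counts vs scaled counts
    np.testing.assert_allclose(h1.to_numpy(), h2.to_numpy(), atol=1e-12)


def test_hellinger_rejects_zero_row():
    with pytest.raises(ValueError, match="bad_sample"):
        bf.hellinger_transform(pd.DataFrame([[0, 0]], index=["bad_sample"]))


def test_env_transform_log_except_ph():
    env = pd.DataFrame({"DOC": [1.0, np.e], "pH": [8.1, 7.0]})
    out = bf.env_transform(env)
    np.testing.assert_allclose(out["DOC"], [0.0, 1.0])
    np.testing.assert_allclose(out["pH"], [8.1, 7.0])
    with pytest.raises(ValueError, match="DOC"):
        bf.env_transform(pd.DataFrame({"DOC": [0.0], "pH": [7.0]}))


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def test_rda_noiseless_proportion_one():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(0, 1, (15, 3)), columns=list("abc"))
    Y = X.to_numpy() @ rng.normal(0, 1, (3, 5))
    res = bf.rda_fit(pd.DataFrame(Y), X)
    assert res.proportion_constrained == pytest.approx(1.0, abs=1e-9)


def test_rda_orthogonal_constraints_explain_little():
    """Y independent of X: constrained share ~ p/(n-1), well below 0.2."""
    rng = np.random.default_rng(1)
    props = []
    for _ in range(20):
        Y = rng.normal(0, 1, (30, 5))
        X = rng.normal(0, 1, (30, 2))
        props.append(bf.rda_fit(pd.DataFrame(Y), pd.DataFrame(X))
                     .proportion_constrained)
    assert np.mean(props) <= 0.2


def test_rda_proportions_partition_unity():
    rng = np.random.default_rng(2)
    Y = rng.normal(0, 1, (20, 4))
    X = rng.normal(0, 1, (20, 3))
    res = bf.rda_fit(pd.DataFrame(Y), pd.DataFrame(X))
    total = res.eigenvalues.sum() + res.unconstrained_eigenvalues.sum()
    var = (Y - Y.mean(0)).var(axis=0, ddof=1).sum()
    assert total == pytest.approx(var, rel=1e-9)


def test_rda_invariant_to_affine_rescaling_of_constraints():
    rng = np.random.default_rng(3)
    Y = pd.DataFrame(rng.normal(0, 1, (20, 4)))
    X = pd.DataFrame(rng.uniform(1, 5, (20, 3)), columns=list("abc"))
    base = bf.rda_fit(Y, X).proportion_constrained
    X2 = X.copy()
    X2["a"] = X2["a"] * 100 - 7      # affine, e.g. a log-base change
    assert bf.rda_fit(Y, X2).proportion_constrained == pytest.approx(
        base, abs=1e-9)


def test_rda_rank_deficiency_mentions_vif():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(0, 1, 12)})
    X["b"] = 2 * X["a"]
    Y = pd.DataFrame(rng.normal(0, 1, (12, 3)))
    with pytest.raises(ValueError, match="VIF"):
        bf.rda_fit(Y, X)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def test_permutation_p_floor_and_perfect_relation():
    """Perfect linear relation at n=20: p hits the 999-permutation floor."""
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(0, 1, (20, 2)))
    Y = pd.DataFrame(X.to_numpy() @ rng.normal(0, 1, (2, 4)))
    res = bf.rda_fit(Y, X)
    res = bf.permutation_tests(res, Y, X, n_perm=999, seed=0)
    assert res.p_model == pytest.approx(1 / 1000)
    assert res.p_model == 0.001  # minimum attainable with 999 permutations
    assert (res.p_terms <= 0.05).all()


def test_permutation_guard():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(0, 1, (10, 2)))
    Y = pd.DataFrame(rng.normal(0, 1, (10, 2)))
    res = bf.rda_fit(Y, X)
    with pytest.raises(ValueError):
        bf.permutation_tests(res, Y, X, n_perm=50)


def test_permutation_pvalues_in_valid_range():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(0, 1, (15, 2)))
    Y = pd.DataFrame(rng.normal(0, 1, (15, 3)))
    res = bf.permutation_tests(bf.rda_fit(Y, X), Y, X, n_perm=99, seed=1)
    for p in [res.p_model, *res.p_axes, *res.p_terms]:
        assert 1 / 100 <= p <= 1


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _driver_data(seed, n=18, strength=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
    Y = pd.DataFrame(
        np.outer(X["a"], [1, 0, 0.5]) * strength + rng.normal(0, 0.15, (n, 3)))
    return Y, X


def test_select_model_keeps_unanimous_variable():
    Y, X = _driver_data(0, strength=2.0)
    selected, audit = bf.select_model(Y, X, seed=0)
    assert "a" in selected
    assert audit.loc["a", "votes"] == 3


def test_select_model_drops_duplicate_by_vif():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(0, 1, (18, 2)), columns=["a", "b"])
    X["a_copy"] = X["a"] + rng.normal(0, 1e-8, 18)
    Y = pd.DataFrame(np.outer(X["a"], [1.0, 0.7]) + rng.normal(0, 0.1, (18, 2)))
    selected, _ = bf.select_model(Y, X, seed=0)
    assert len({"a", "a_copy"} & set(selected)) == 1  # one of the twins survives


def test_vif_unbounded_for_duplicates():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"a": rng.normal(0, 1, 20)})
    X["b"] = X["a"]
    X["c"] = rng.normal(0, 1, 20)
    vif = variance_inflation_factors(X)
    assert np.isinf(vif["a"]) and np.isinf(vif["b"])
    assert vif["c"] < 10


def test_select_model_empty_result_warns():
    rng = np.random.default_rng(3)
    Y = pd.DataFrame(rng.normal(0, 1, (15, 3)))
    X = pd.DataFrame(rng.normal(0, 1, (15, 3)), columns=list("abc"))
    with pytest.warns(UserWarning, match="empty"):
        selected, _ = bf.select_model(Y, X, seed=4)
    assert selected == []


# ---------------------------------------------------------------------------
# Vector fitting
# ---------------------------------------------------------------------------

def test_vector_fit_axis_aligned_and_diagonal():
    rng = np.random.default_rng(8)
    scores = rng.normal(0, 1, (25, 2))
    scores = scores - scores.mean(0)
    env = pd.DataFrame({
        "axis1_var": scores[:, 0],
        "diag_var": scores[:, 0] + scores[:, 1],
    })
    fit = bf.vector_fit(scores, env, n_perm=99, seed=0)
    assert fit.loc["axis1_var", "r2"] == pytest.approx(1.0)
    assert abs(fit.loc["axis1_var", "dx"]) == pytest.approx(1.0)
    assert fit.loc["axis1_var", "dy"] == pytest.approx(0.0, abs=1e-9)
    assert fit.loc["diag_var", "r2"] == pytest.approx(1.0)
    d = np.array([fit.loc["diag_var", "dx"], fit.loc["diag_var", "dy"]])
    # direction proportional to (1,1)/sqrt(2) up to overall sign
    np.testing.assert_allclose(np.abs(d), 1 / np.sqrt(2), atol=1e-6)


def test_vector_fit_noise_variable_not_significant():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        scores = rng.normal(0, 1, (20, 2))
        env = pd.DataFrame({"noise": rng.normal(0, 1, 20)})
        fit = bf.vector_fit(scores, env, n_perm=99, seed=seed)
        hits += fit.loc["noise", "p"] <= 0.05
    assert hits <= 10  # p uniform under the null: > 0.05 in >= 90% of sims


def test_vector_fit_constant_variable():
    rng = np.random.default_rng(9)
    scores = rng.normal(0, 1, (10, 2))
    with pytest.warns(UserWarning, match="constant"):
        fit = bf.vector_fit(scores, pd.DataFrame({"c": np.ones(10)}), n_perm=99)
    assert fit.loc["c", "r2"] == 0.0


# ---------------------------------------------------------------------------
# ANOVA + Tukey + Holm
# ---------------------------------------------------------------------------

def test_holm_stepdown_arithmetic():
    np.testing.assert_allclose(bf.holm_adjust([0.01, 0.04]), [0.02, 0.04])
    np.testing.assert_allclose(bf.holm_adjust([0.03, 0.01, 0.04]),
                               [0.06, 0.03, 0.06])


def test_anova_identical_groups():
    table = pd.DataFrame({"sub1": [0.5] * 6, "sub2": [0.25] * 6})
    res = bf.anova_tukey_holm(table, ["a", "a", "b", "b", "c", "c"])
    assert (res["anova"]["F"] == 0).all()
    assert (res["anova"]["p"] == 1).all()
    assert (res["pairwise"]["p_holm"] == 1).all()


def test_anova_strong_separation_detected():
    """Two groups 10 within-group SDs apart, n=5: adjusted p < 0.01."""
    rng = np.random.default_rng(10)
    sd = 0.01
    a = rng.normal(0.3, sd, 5)
    b = rng.normal(0.3 + 10 * sd, sd, 5)
    table = pd.DataFrame({"sub": np.concatenate([a, b])})
    res = bf.anova_tukey_holm(table, ["g1"] * 5 + ["g2"] * 5)
    assert res["anova"].loc["sub", "p"] < 0.01
    assert (res["pairwise"]["p_holm"] < 0.01).all()


def test_anova_requires_replicates():
    table = pd.DataFrame({"s": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="replicates"):
        bf.anova_tukey_holm(table, ["a", "a", "b"])


def test_tukey_holm_three_groups_orders_sensibly():
    rng = np.random.default_rng(11)
    vals = np.concatenate([rng.normal(0.2, 0.02, 4),
                           rng.normal(0.2, 0.02, 4),
                           rng.normal(0.5, 0.02, 4)])
    table = pd.DataFrame({"sub": vals})
    res = bf.anova_tukey_holm(table, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    pw = res["pairwise"].set_index(["group_a", "group_b"])
    assert pw.loc[("a", "b"), "p_holm"] > 0.05
    assert pw.loc[("a", "c"), "p_holm"] < 0.01
    assert pw.loc[("b", "c"), "p_holm"] < 0.01
    assert (res["pairwise"]["p_holm"] >= res["pairwise"]["p_tukey"] - 1e-12).all()
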