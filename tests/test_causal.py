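import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, softmax

from osipheno import causal


def _confounded_threeclass(n=2500, seed=0, scale=0.4):
    rng = np.random.default_rng(seed)
    p = 4
    x = rng.standard_normal((n, p))
    B = scale * np.array(
        [[0.0] * p, [1.2, -0.8, 1.0, 0.6], [-1.0, 1.0, 0.6, -0.8]]
    ).T
    probs = softmax(x @ B, axis=1)
    u = rng.random(n)
    z = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    return pd.DataFrame(x, columns=[f"c{j}" for j in range(p)]), z


# ---------------------------------------------------------------------------
# propensity + weights


def test_propensity_rows_sum_to_one():
    X, z = _confounded_threeclass(n=600)
    prop = causal.fit_propensity(X, z)
    assert prop.shape == (600, 3)
    np.testing.assert_allclose(prop.sum(axis=1), 1.0, atol=1e-10)
    assert prop.min() >= causal.PROPENSITY_CLIP / 2


def test_propensity_gradient_boosting():
    X, z = _confounded_threeclass(n=600)
    prop = causal.fit_propensity(X, z, method="gradient_boosting", seed=0)
    np.testing.assert_allclose(prop.sum(axis=1), 1.0, atol=1e-6)


def test_propensity_rejects_nan():
    X, z = _confounded_threeclass(n=100)
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError):
        causal.fit_propensity(X, z)


def test_iptw_is_inverse_assigned_propensity():
    X, z = _confounded_threeclass(n=500)
    prop = causal.fit_propensity(X, z)
    w = causal.compute_iptw(prop, z)
    e_assigned = prop[np.arange(len(z)), z]
    np.testing.assert_allclose(w, 1.0 / e_assigned)


def test_stabilized_weights_scale_by_marginal_share():
    X, z = _confounded_threeclass(n=500)
    prop = causal.fit_propensity(X, z)
    w = causal.compute_iptw(prop, z)
    ws = causal.compute_iptw(prop, z, stabilized=True)
    shares = np.bincount(z) / len(z)
    np.testing.assert_allclose(ws, w * shares[z])


def test_truncated_weights_are_capped():
    X, z = _confounded_threeclass(n=500)
    prop = causal.fit_propensity(X, z)
    w = causal.compute_iptw(prop, z)
    wt = causal.compute_iptw(prop, z, truncate_pct=5.0)
    lo, hi = np.percentile(w, [5.0, 95.0])
    assert wt.max() <= hi + 1e-12 and wt.min() >= lo - 1e-12


# ---------------------------------------------------------------------------
# SMD


def test_smd_identical_groups_zero():
    x = np.concatenate([np.arange(10.0)] * 2)
    g = np.repeat([0, 1], 10)
    assert causal.compute_smd(x, g) == 0.0


def test_smd_unit_gap_unit_sd():
    # ddof-1 SD of {-s, s} is s * sqrt(2); s = 1/sqrt(2) gives SD exactly 1
    s = 1.0 / np.sqrt(2.0)
    x = np.array([-s, s, 1 - s, 1 + s])
    g = np.array([0, 0, 1, 1])
    assert causal.compute_smd(x, g) == pytest.approx(1.0)


def test_smd_binary_formula():
    x = np.concatenate([np.repeat([0.0, 1.0], [50, 50]), np.repeat([0.0, 1.0], [40, 60])])
    g = np.repeat([0, 1], 100)
    expected = 0.1 / np.sqrt((0.25 + 0.24) / 2.0)
    assert causal.compute_smd(x, g) == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(0.20203, abs=1e-5)


def test_smd_max_over_pairs():
    x = np.concatenate([np.zeros(20), np.zeros(20), np.ones(20)])
    g = np.repeat([0, 1, 2], 20)
    assert causal.compute_smd(x, g, binary=True) == causal.compute_smd(
        x[20:], g[20:], binary=True
    )


def test_smd_degenerate_variance_inf():
    x = np.repeat([0.0, 1.0], 5)
    g = np.repeat([0, 1], 5)
    assert causal.compute_smd(x, g, binary=False) == np.inf


def test_smd_single_group_rejected():
    with pytest.raises(ValueError):
        causal.compute_smd(np.arange(4.0), np.zeros(4))


def test_weighting_improves_balance_under_correct_model():
    X, z = _confounded_threeclass(n=2500, seed=1)
    wc = causal.weight_cohort(X, z, seed=0)
    before = (wc.smd_before["smd"] > 0.1).sum()
    after = (wc.smd_after["smd"] > 0.1).sum()
    assert before > 0 and after < before
    assert set(wc.unbalanced_covariates) == set(
        wc.smd_after.index[wc.smd_after["smd"] > 0.1]
    )


# ---------------------------------------------------------------------------
# doubly robust outcome model


def test_dr_unit_weights_match_unweighted_logit():
    rng = np.random.default_rng(4)
    n = 800
    z = rng.integers(0, 3, n)
    x = rng.standard_normal(n)
    y = (rng.random(n) < expit(-1.0 + 0.5 * (z == 2) + 0.4 * x)).astype(int)
    adj = pd.DataFrame({"x": x})
    est = causal.dr_estimate(y, z, weights=None, adjustment=adj)
    design = np.column_stack(
        [np.ones(n), (z == 1).astype(float), (z == 2).astype(float), (x - x.mean()) / x.std()]
    )
    ref = sm.Logit(y, design).fit(disp=0)
    np.testing.assert_allclose(est.params, ref.params, atol=1e-5)


def test_dr_estimate_recovers_known_effect():
    rng = np.random.default_rng(5)
    n = 6000
    z = rng.integers(0, 2, n)
    y = (rng.random(n) < expit(-1.0 + 0.8 * z)).astype(int)
    est = causal.dr_estimate(y, z)
    row = est.table.loc["1_vs_0"]
    assert row["ci_low"] < np.exp(0.8) < row["ci_high"]


def test_dr_estimate_reference_class():
    rng = np.random.default_rng(6)
    z = rng.integers(0, 3, 300)
    y = rng.integers(0, 2, 300)
    est = causal.dr_estimate(y, z, reference=2)
    assert set(est.table.index) == {"0_vs_2", "1_vs_2"}


def test_dr_estimate_rejects_nonbinary_outcome():
    with pytest.raises(ValueError):
        causal.dr_estimate(np.array([0, 1, 2]), np.array([0, 1, 0]))


def test_dr_table_variants(small_cohort):
    from osipheno import synth

    covars = small_cohort.baseline[list(synth.DAG_COVARIATES)]
    labels = small_cohort.true_class
    wc = causal.weight_cohort(covars, labels, stabilized=True, seed=0)
    death = small_cohort.baseline["icu_death"].to_numpy(int)
    tables = causal.dr_table(death, labels, covars, wc)
    assert set(tables) == {"iptw", "dr_unbalanced", "dr_all"}
    for est in tables.values():
        assert {"or", "ci_low", "ci_high", "p"} <= set(est.table.columns)
        assert (est.table["or"] > 0).all()


# ---------------------------------------------------------------------------
# VIF / subgroup


def test_vif_exact_value():
    rng = np.random.default_rng(7)
    n = 200
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    # orthonormalize in-sample so the R^2 of x2 on x1 is exactly 0.81
    u = (u - u.mean()) / u.std()
    v = v - v.mean()
    v -= (v @ u) / (u @ u) * u
    v /= v.std()
    x2 = 0.9 * u + np.sqrt(1 - 0.81) * v
    table = causal.vif_check(pd.DataFrame({"x1": u, "x2": x2}))
    np.testing.assert_allclose(table["vif"], 1.0 / (1.0 - 0.81), rtol=1e-6)
    assert table["flagged"].all()  # 5.26 > 5


def test_vif_duplicate_column_infinite():
    x = np.arange(50.0)
    table = causal.vif_check(pd.DataFrame({"a": x, "b": x}))
    assert np.isinf(table["vif"]).all()


def test_vif_independent_near_one():
    rng = np.random.default_rng(8)
    table = causal.vif_check(pd.DataFrame(rng.standard_normal((2000, 3)), columns=list("abc")))
    assert (table["vif"] < 1.1).all()
    assert not table["flagged"].any()


def test_subgroup_analysis_runs():
    rng = np.random.default_rng(9)
    n = 1200
    z = rng.integers(0, 2, n)
    strat = rng.integers(0, 2, n)
    x = rng.standard_normal(n)
    y = (rng.random(n) < expit(-1 + 0.6 * z + 0.2 * x)).astype(int)
    out = causal.subgroup_analysis(y, z, strat)
    assert set(out["per_stratum"]) == {0, 1}
    assert 0.0 <= out["interaction_p"] <= 1.0
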