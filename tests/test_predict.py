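import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from itertools import combinations
from scipy.special import expit

from osipheno import predict


# ---------------------------------------------------------------------------
# SMOTE


def _imbalanced(n_min=15, n_maj=60, seed=0, p=3):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, (n_maj, p)), rng.normal(3, 1, (n_min, p))])
    y = np.concatenate([np.zeros(n_maj, int), np.ones(n_min, int)])
    return x, y


def test_smote_equalizes_counts():
    x, y = _imbalanced()
    xr, yr = predict.smote(x, y, seed=1)
    counts = np.bincount(yr)
    assert counts[0] == counts[1] == 60
    # originals preserved as a prefix
    np.testing.assert_allclose(xr[: len(x)], x)


def test_smote_points_lie_on_minority_segments():
    x, y = _imbalanced()
    xr, yr = predict.smote(x, y, seed=2)
    minority = x[y == 1]
    for pt in xr[len(x):]:
        on_segment = False
        for a, b in combinations(minority, 2):
            d = b - a
            denom = d @ d
            if denom == 0:
                continue
            u = (pt - a) @ d / denom
            if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(a + u * d - pt) < 1e-8:
                on_segment = True
                break
        assert on_segment


def test_smote_balanced_input_unchanged():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(20, 2))
    y = np.repeat([0, 1], 10)
    xr, yr = predict.smote(x, y)
    np.testing.assert_allclose(xr, x)
    np.testing.assert_array_equal(yr, y)


def test_smote_small_minority_reduces_k_with_warning():
    x, y = _imbalanced(n_min=4, n_maj=20)
    with pytest.warns(UserWarning, match="k reduced"):
        xr, yr = predict.smote(x, y, k=5)
    assert np.bincount(yr)[1] == 20


def test_smote_single_minority_member_rejected():
    x, y = _imbalanced(n_min=1, n_maj=10)
    with pytest.raises(ValueError):
        predict.smote(x, y)


# ---------------------------------------------------------------------------
# LASSO


def _logistic_data(n=300, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 4))
    eta = -0.3 + 1.2 * x[:, 0] - 0.8 * x[:, 1]  # features 2, 3 are noise
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(x, columns=list("abcd")), y


def test_lasso_zero_penalty_matches_unpenalized():
    X, y = _logistic_data()
    out = predict.lasso_select(X, y, lambda_grid=[0.0], folds=3, seed=0)
    z = (X - X.mean()) / X.std(ddof=0)
    ref = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
    np.testing.assert_allclose(out["coef"], ref.params.iloc[1:], atol=1e-4)
    assert out["intercept"] == pytest.approx(ref.params.iloc[0], abs=1e-4)


def test_lasso_screens_noise_features():
    X, y = _logistic_data(n=600, seed=1)
    out = predict.lasso_select(X, y, folds=5, seed=0)
    assert {"a", "b"} <= set(out["selected"])


def test_lasso_heavy_penalty_kills_everything():
    X, y = _logistic_data()
    out = predict.lasso_select(X, y, lambda_grid=[10.0], folds=3, seed=0)
    assert out["selected"] == []


def test_lasso_path_shrinks_with_penalty():
    X, y = _logistic_data()
    out = predict.lasso_select(X, y, lambda_grid=np.geomspace(1.0, 1e-3, 8), folds=3, seed=0)
    norms = np.abs(out["coef_path"]).sum(axis=1)
    assert norms[0] <= norms[-1] + 1e-8  # grid is descending in penalty


# ---------------------------------------------------------------------------
# nomogram


def test_nomogram_round_trip_exact():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.uniform(0, 10, (50, 3)), columns=list("xyz"))
    coef = np.array([0.3, -0.5, 0.05])
    nomo = predict.build_nomogram(coef, intercept=-1.0, features=X)
    direct = expit(-1.0 + X.to_numpy() @ coef)
    np.testing.assert_allclose(nomo.predict_risk(X.to_numpy()), direct, atol=1e-9)


def test_nomogram_points_nonnegative_and_scaled():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.uniform(0, 1, (40, 2)), columns=list("ab"))
    nomo = predict.build_nomogram(np.array([2.0, -1.0]), 0.0, X)
    pts = nomo.points(X.to_numpy())
    assert pts.min() >= -1e-9
    assert pts.max() == pytest.approx(100.0, abs=1e-6)  # dominant feature spans 0-100


def test_nomogram_drops_constant_feature():
    X = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
    with pytest.warns(UserWarning, match="zero-range"):
        nomo = predict.build_nomogram(np.array([1.0, 1.0]), 0.0, X)
    assert nomo.feature_names == ["a"]


# ---------------------------------------------------------------------------
# AUC / DeLong


def test_auc_pairwise_oracle_with_ties():
    rng = np.random.default_rng(6)
    scores = np.round(rng.random(20), 1)  # coarse grid forces ties
    labels = rng.integers(0, 2, 20)
    labels[0], labels[1] = 0, 1  # both classes present
    pos, neg = scores[labels == 1], scores[labels == 0]
    oracle = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
    assert predict.auc_rank(scores, labels) == pytest.approx(oracle, abs=1e-12)


def test_auc_perfect_and_chance():
    y = np.repeat([0, 1], 10)
    assert predict.auc_rank(np.arange(20.0), y) == 1.0
    assert predict.auc_rank(np.zeros(20), y) == 0.5


def test_delong_ci_brackets_auc():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, 200)
    s = y + rng.normal(0, 1, 200)
    auc, lo, hi, se = predict.delong_ci(s, y)
    assert 0 <= lo <= auc <= hi <= 1 and se > 0
    assert auc == pytest.approx(predict.auc_rank(s, y))


# ---------------------------------------------------------------------------
# calibration + decision curve


def test_hosmer_lemeshow_df_and_detection():
    rng = np.random.default_rng(8)
    n = 2000
    p = rng.uniform(0.05, 0.95, n)
    y_good = (rng.random(n) < p).astype(int)
    good = predict.hosmer_lemeshow(p, y_good)
    assert good["df"] == 8
    # gross miscalibration must be detected
    y_bad = (rng.random(n) < np.clip(p + 0.25, 0, 1)).astype(int)
    bad = predict.hosmer_lemeshow(p, y_bad)
    assert bad["p_value"] < 1e-6
    assert bad["statistic"] > good["statistic"]


def test_hosmer_lemeshow_merges_tied_bins():
    p = np.repeat([0.2, 0.8], 50)
    y = (np.random.default_rng(9).random(100) < p).astype(int)
    out = predict.hosmer_lemeshow(p, y)
    assert out["df"] >= 1 and np.isfinite(out["statistic"])


def test_decision_curve_treat_none_zero():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 150)
    p = rng.random(150)
    dc = predict.decision_curve(p, y)
    assert (dc["net_benefit_none"] == 0.0).all()


def test_decision_curve_perfect_model():
    y = np.repeat([0, 1], 50)
    dc = predict.decision_curve(y.astype(float), y)
    # a perfect model's net benefit equals prevalence at every threshold < 1
    np.testing.assert_allclose(dc["net_benefit_model"], 0.5, atol=1e-12)


def test_decision_curve_treat_all_formula():
    rng = np.random.default_rng(11)
    y = rng.integers(0, 2, 200)
    prev = y.mean()
    dc = predict.decision_curve(rng.random(200), y, thresholds=[0.25])
    assert dc["net_benefit_all"].iloc[0] == pytest.approx(prev - (1 - prev) / 3)


# ---------------------------------------------------------------------------
# end-to-end trainer


def test_train_poor_prognosis_model_smoke():
    rng = np.random.default_rng(12)
    n = 600
    x = rng.standard_normal((n, 5))
    eta = -1.5 + 1.0 * x[:, 0] + 0.8 * x[:, 1]
    y = (rng.random(n) < expit(eta)).astype(int)
    X = pd.DataFrame(x, columns=[f"f{j}" for j in range(5)])
    cut = 400
    rep = predict.train_poor_prognosis_model(
        X.iloc[:cut], y[:cut], X.iloc[cut:], y[cut:], folds=4, seed=0
    )
    assert rep["train_eval"]["auc"] > 0.7
    assert rep["valid_eval"]["auc"] > 0.65
    assert isinstance(rep["nomogram"], predict.NomogramModel)
    assert rep["selected"]
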