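import numpy as np
import pytest
from types import SimpleNamespace

from osipheno import gbtm, synth
from osipheno.containers import TrajectoryMatrix
from conftest import matched_accuracy


def _two_class_matrix(n=300, seed=0, sep=4.0, noise=1.0):
    rng = np.random.default_rng(seed)
    grid = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
    lab = (rng.random(n) < 0.4).astype(int)
    mu = np.where(lab == 0, 5.0, 5.0 + sep)
    y = mu[:, None] + noise * rng.standard_normal((n, 5))
    y = np.clip(y, 0.1, None)
    return TrajectoryMatrix(np.arange(n), grid, y), lab


def test_single_class_order0_closed_form():
    tm, _ = _two_class_matrix(n=50, seed=1, sep=0.0)
    fit = gbtm.TrajectoryGBTM(n_classes=1, orders=0, n_starts=1, seed=0).fit(tm)
    y = tm.osi
    mu = y.mean()
    sig2 = ((y - mu) ** 2).mean()
    assert fit.beta_[0][0] == pytest.approx(mu, abs=1e-6)
    assert fit.sigma_**2 == pytest.approx(sig2, rel=1e-5)
    ll = -0.5 * y.size * (np.log(2 * np.pi * sig2) + 1.0)
    assert fit.loglik_ == pytest.approx(ll, rel=1e-8)


def test_loglik_monotone_nondecreasing():
    tm, _ = _two_class_matrix(seed=2)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=1, n_starts=3, seed=0).fit(tm)
    path = np.asarray(fit.loglik_path_)
    assert np.all(np.diff(path) >= -1e-6)


def test_two_class_recovery():
    tm, lab = _two_class_matrix(seed=3)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=0, n_starts=5, seed=0).fit(tm)
    pred = fit.predict(tm)
    assert matched_accuracy(lab, pred, 2) > 0.95


def test_posterior_rows_sum_to_one():
    tm, _ = _two_class_matrix(seed=4)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=1, n_starts=3, seed=0).fit(tm)
    np.testing.assert_allclose(fit.posterior_.sum(axis=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(fit.predict_proba(tm).sum(axis=1), 1.0, atol=1e-10)


def test_canonical_order_by_mean_level():
    tm, _ = _two_class_matrix(seed=5)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=0, n_starts=5, seed=0).fit(tm)
    curves = fit.mean_curves()
    assert curves[0].mean() < curves[1].mean()


def test_seed_invariant_solution():
    # different starts converge to the same canonical solution
    tm, _ = _two_class_matrix(seed=6)
    f1 = gbtm.TrajectoryGBTM(n_classes=2, orders=1, n_starts=5, seed=0).fit(tm)
    f2 = gbtm.TrajectoryGBTM(n_classes=2, orders=1, n_starts=5, seed=99).fit(tm)
    np.testing.assert_allclose(f1.pi_, f2.pi_, atol=1e-4)
    np.testing.assert_allclose(f1.mean_curves(), f2.mean_curves(), atol=1e-3)


def test_nested_orders_increase_loglik():
    tm, _ = _two_class_matrix(seed=7)
    ll = [
        gbtm.TrajectoryGBTM(n_classes=2, orders=o, n_starts=5, seed=0).fit(tm).loglik_
        for o in (0, 1, 2)
    ]
    assert ll[0] <= ll[1] + 1e-6 and ll[1] <= ll[2] + 1e-6


def test_missing_cells_handled():
    tm, lab = _two_class_matrix(seed=8)
    rng = np.random.default_rng(0)
    drop = rng.random(tm.osi.shape) < 0.2
    osi = tm.osi.copy()
    osi[drop] = np.nan
    tm2 = TrajectoryMatrix(tm.patient_ids, tm.grid_hours, osi)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=0, n_starts=5, seed=0).fit(tm2)
    assert matched_accuracy(lab, fit.predict(tm2), 2) > 0.9


def test_insufficient_observations_rejected():
    grid = np.array([0.0, 24.0, 48.0])
    osi = np.array([[5.0, np.nan, np.nan], [5.0, 6.0, 7.0]])
    tm = TrajectoryMatrix(np.array([0, 1]), grid, osi)
    with pytest.raises(ValueError):
        gbtm.TrajectoryGBTM(n_classes=1, orders=2, n_starts=1, seed=0).fit(tm)


def test_invalid_order_rejected():
    tm, _ = _two_class_matrix(n=20)
    with pytest.raises(ValueError):
        gbtm.TrajectoryGBTM(n_classes=1, orders=5, n_starts=1, seed=0).fit(tm)


# ---------------------------------------------------------------------------
# diagnostics


def _fake_fit(posterior, loglik=-100.0, n_params=5):
    return SimpleNamespace(
        posterior_=np.asarray(posterior, dtype=float),
        loglik_=loglik,
        n_params_=n_params,
    )


def test_bic_formula():
    tm, _ = _two_class_matrix(seed=9)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=1, n_starts=3, seed=0).fit(tm)
    d = gbtm.diagnostics(fit)
    assert d["bic"] == pytest.approx(-2 * fit.loglik_ + fit.n_params_ * np.log(tm.n_patients))
    assert d["minus2ll"] == pytest.approx(-2 * fit.loglik_)


def test_entropy_bounds():
    crisp = gbtm.diagnostics(_fake_fit(np.tile([1.0, 0.0], (10, 1))))
    assert crisp["entropy"] == pytest.approx(1.0)
    fuzzy = gbtm.diagnostics(_fake_fit(np.tile([0.5, 0.5], (10, 1))))
    assert fuzzy["entropy"] == pytest.approx(0.0, abs=1e-9)


def test_single_class_entropy_is_one():
    d = gbtm.diagnostics(_fake_fit(np.ones((7, 1))))
    assert d["entropy"] == 1.0


def test_app_and_share():
    post = np.array([[0.9, 0.1]] * 8 + [[0.2, 0.8]] * 2)
    d = gbtm.diagnostics(_fake_fit(post))
    np.testing.assert_allclose(d["share"], [0.8, 0.2])
    np.testing.assert_allclose(d["app"], [0.9, 0.8])


def test_admissibility_reasons():
    ok = {"share": np.array([0.5, 0.5]), "app": np.array([0.9, 0.95])}
    assert gbtm.admissibility(ok) == (True, "")
    small = {"share": np.array([0.97, 0.03]), "app": np.array([0.9, 0.95])}
    assert gbtm.admissibility(small) == (False, "share<5%")
    weak = {"share": np.array([0.5, 0.5]), "app": np.array([0.9, 0.6])}
    assert gbtm.admissibility(weak) == (False, "APP<0.7")
    both = {"share": np.array([0.97, 0.03]), "app": np.array([0.9, 0.6])}
    assert gbtm.admissibility(both) == (False, "share<5%;APP<0.7")
    empty = {"share": np.array([1.0, 0.0]), "app": np.array([0.9, np.nan])}
    assert gbtm.admissibility(empty)[0] is False


# ---------------------------------------------------------------------------
# model selection


def test_select_model_picks_two_classes():
    tm, _ = _two_class_matrix(n=250, seed=10)
    report = gbtm.select_model(tm, k_range=(2, 3), seed=0, n_starts=5)
    assert report.chosen_k == 2
    assert all(o >= 1 for o in report.final_fit.orders_)
    assert report.to_dict()["chosen_k"] == 2


def test_select_model_shape_refinement_drops_flat_terms():
    # flat trajectories: cubic and quadratic terms should be pruned to linear
    tm, _ = _two_class_matrix(n=250, seed=11)
    report = gbtm.select_model(tm, k_range=(2,), seed=0, n_starts=5)
    assert list(report.final_fit.orders_) == [1, 1]


def test_select_model_no_admissible_candidate_raises():
    # one tight cluster: a forced 2-class split leaves a tiny or fuzzy class
    rng = np.random.default_rng(12)
    grid = np.array([0.0, 24.0, 48.0])
    y = 6.0 + 0.05 * rng.standard_normal((80, 3))
    tm = TrajectoryMatrix(np.arange(80), grid, y)
    with pytest.raises(RuntimeError, match="admissible"):
        gbtm.select_model(tm, k_range=(2,), seed=0, n_starts=3)


def test_assign_phenotypes_matches_argmax():
    tm, _ = _two_class_matrix(seed=13)
    fit = gbtm.TrajectoryGBTM(n_classes=2, orders=0, n_starts=3, seed=0).fit(tm)
    labels, post = gbtm.assign_phenotypes(fit)
    np.testing.assert_array_equal(labels, np.argmax(post, axis=1))
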