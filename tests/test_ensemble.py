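"""Stacking ensemble: bootstrap stage, combiners, LASSO/PLSR oracles."""

import numpy as np
import pytest

from esrstack.basemodels import ArchitectureSpec, TrainConfig, WindowSet
from esrstack.ensemble import (
    ForecastMatrix,
    MetaModel,
    bootstrap_indices,
    combine_mean,
    combine_median,
    fit_lasso,
    fit_plsr,
    fit_stacking,
    lambda_path,
)


def ols_predictions(Z, y, Z_new=None):
    """Independent least-squares oracle (normal equations with intercept)."""
    Z_new = Z if Z_new is None else Z_new
    A = np.column_stack([np.ones(len(Z)), Z])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.column_stack([np.ones(len(Z_new)), Z_new]) @ beta


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_single_element(rng):
    assert bootstrap_indices(1, rng).tolist() == [0]
    with pytest.raises(ValueError):
        bootstrap_indices(0, rng)


def test_bootstrap_unique_fraction_near_632():
    idx = bootstrap_indices(10000, np.random.default_rng(0))
    frac = np.unique(idx).size / 10000
    assert 0.62 <= frac <= 0.65


def test_bootstrap_reproducible():
    a = bootstrap_indices(50, np.random.default_rng(3))
    b = bootstrap_indices(50, np.random.default_rng(3))
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# simple combiners

def test_mean_and_median_trivial_rows():
    Z = np.array([[0.4, 0.6]])
    assert combine_mean(Z)[0] == pytest.approx(0.5)
    assert combine_median(np.array([[0.4, 0.5, 0.9]]))[0] == pytest.approx(0.5)
    assert combine_median(np.array([[0.1, 0.2, 0.8, 0.9]]))[0] == pytest.approx(0.5)


def test_combiners_match_sort_based_oracles(rng):
    Z = rng.normal(size=(40, 7))
    np.testing.assert_allclose(combine_mean(Z), Z.sum(axis=1) / 7.0, atol=1e-12)
    Zs = np.sort(Z, axis=1)
    np.testing.assert_allclose(combine_median(Z), Zs[:, 3], atol=1e-12)


def test_mean_equals_median_for_identical_columns(rng):
    col = rng.normal(size=30)
    Z = np.column_stack([col] * 5)
    np.testing.assert_allclose(combine_mean(Z), combine_median(Z), atol=1e-12)


def test_forecast_matrix_validation(rng):
    with pytest.raises(ValueError):
        ForecastMatrix(np.ones((3, 2)), np.ones(4))
    with pytest.raises(ValueError):
        ForecastMatrix(np.array([[np.nan, 1.0]]), np.ones(1))


# ---------------------------------------------------------------------------
# LASSO

def test_lasso_at_zero_penalty_matches_ols(rng):
    Z = rng.normal(size=(60, 4))
    y = Z @ np.array([0.3, -0.2, 0.5, 0.1]) + 0.4 + rng.normal(0, 0.05, 60)
    meta = fit_lasso(Z, y, lambda_grid=np.array([1e-10]), rng=0)
    np.testing.assert_allclose(meta.predict(Z), ols_predictions(Z, y), atol=1e-6)


def test_lasso_full_shrinkage_predicts_mean(rng):
    Z = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    lam = 10.0 * lambda_path(Z, y)[0]  # well above lambda_max
    meta = fit_lasso(Z, y, lambda_grid=np.array([lam]), rng=0)
    np.testing.assert_allclose(meta.coef, 0.0, atol=1e-10)
    np.testing.assert_allclose(meta.predict(Z), y.mean(), atol=1e-10)


def test_lasso_single_predictor_soft_threshold(rng):
    """beta equals the closed-form soft-thresholded OLS coefficient."""
    z = rng.normal(size=80)
    z = (z - z.mean()) / z.std()
    y = 0.7 * z + rng.normal(0, 0.1, 80)
    lam = 20.0
    meta = fit_lasso(z[:, None], y, lambda_grid=np.array([lam]), rng=0)
    zc = z - z.mean()
    yc = y - y.mean()
    rho = zc @ yc
    expected = np.sign(rho) * max(abs(rho) - lam / 2.0, 0.0) / (zc @ zc)
    assert meta.coef[0] == pytest.approx(expected, abs=1e-6)


def test_lasso_cv_is_reproducible_and_on_grid(rng):
    Z = rng.normal(size=(50, 5))
    y = Z[:, 0] + rng.normal(0, 0.2, 50)
    grid = lambda_path(Z, y, n_values=20)
    m1 = fit_lasso(Z, y, lambda_grid=grid, rng=4)
    m2 = fit_lasso(Z, y, lambda_grid=grid, rng=4)
    assert m1.lambda_ == m2.lambda_
    assert m1.lambda_ in grid
    assert m1.cv_curve == m2.cv_curve


# ---------------------------------------------------------------------------
# PLSR

def test_plsr_with_all_components_matches_ols(rng):
    Z = rng.normal(size=(50, 4))
    y = Z @ np.array([0.2, -0.4, 0.3, 0.6]) + 1.0 + rng.normal(0, 0.05, 50)
    meta = fit_plsr(Z, y, J_grid=[4], rng=0)
    np.testing.assert_allclose(meta.predict(Z), ols_predictions(Z, y), atol=1e-6)


def test_plsr_single_component_fits_rank_one_signal(rng):
    """y a linear function of Z's dominant direction: J=1 residual ~ 0."""
    t = rng.normal(size=60)
    direction = np.array([0.5, -0.3, 0.8])
    Z = np.outer(t, direction)
    y = 2.0 * t + 0.3
    meta = fit_plsr(Z, y, J_grid=[1], rng=0)
    assert np.max(np.abs(meta.predict(Z) - y)) < 1e-8


def test_plsr_identical_columns_reduce_to_univariate_regression(rng):
    col = rng.normal(size=40)
    Z = np.column_stack([col] * 6)
    y = 0.5 * col + 0.2 + rng.normal(0, 0.01, 40)
    meta = fit_plsr(Z, y, rng=0)
    assert meta.n_components == 1
    np.testing.assert_allclose(meta.predict(Z), ols_predictions(col[:, None], y), atol=1e-8)


def test_plsr_training_residual_non_increasing_in_components(rng):
    Z = rng.normal(size=(60, 6))
    y = rng.normal(size=60)
    resid = []
    for J in range(1, 7):
        meta = fit_plsr(Z, y, J_grid=[J], rng=0)
        resid.append(np.linalg.norm(meta.predict(Z) - y))
    assert all(r2 <= r1 + 1e-9 for r1, r2 in zip(resid, resid[1:]))


def test_regularized_combiners_beat_mean_on_collinear_forecasts(rng):
    """Bases sharing a systematic bias: LASSO/PLSR correct it, mean cannot."""
    results = {"mean": [], "lasso": [], "plsr": []}
    for rep in range(10):
        r = np.random.default_rng(rep)
        y_val = r.uniform(0.35, 0.86, 40)
        y_test = r.uniform(0.35, 0.86, 40)
        bias = r.normal(0.05, 0.02, 6)  # per-base systematic offset
        make_Z = lambda y: np.column_stack(
            [y + b + r.normal(0, 0.02, len(y)) for b in bias]
        )
        Z_val, Z_test = make_Z(y_val), make_Z(y_test)
        results["mean"].append(np.mean((combine_mean(Z_test) - y_test) ** 2))
        for kind, fit in (("lasso", fit_lasso), ("plsr", fit_plsr)):
            meta = fit(Z_val, y_val, rng=rep)
            results[kind].append(np.mean((meta.predict(Z_test) - y_test) ** 2))
    assert np.median(results["lasso"]) <= np.median(results["mean"])
    assert np.median(results["plsr"]) <= np.median(results["mean"])


# ---------------------------------------------------------------------------
# stacking

def _windows(n, seed):
    rng = np.random.default_rng(seed)
    X = np.sort(rng.uniform(0.5, 1.0, size=(n, 11)))[:, ::-1].copy()
    y = np.clip(X[:, -1] - rng.uniform(0.05, 0.3, n), 0.3, 0.9)
    return WindowSet(X, y, [f"s{seed}_{i}" for i in range(n)], 5.0)


def test_single_base_mean_stack_equals_the_base():
    cfg = TrainConfig(max_epochs=10, patience=5, seed=0)
    train, val, test = _windows(20, 0), _windows(8, 1), _windows(6, 2)
    ens, pred = fit_stacking(ArchitectureSpec("MLP"), 1, "mean", train, val, test,
                             config=cfg, rng=3)
    from esrstack.basemodels import predict as base_predict

    np.testing.assert_allclose(pred, base_predict(ens.bases[0], test), atol=1e-12)


def test_stacking_reproducible_under_fixed_seed():
    cfg = TrainConfig(max_epochs=10, patience=5, seed=0)
    train, val, test = _windows(20, 0), _windows(8, 1), _windows(6, 2)
    _, p1 = fit_stacking(ArchitectureSpec("MLP"), 3, "median", train, val, test,
                         config=cfg, rng=5)
    _, p2 = fit_stacking(ArchitectureSpec("MLP"), 3, "median", train, val, test,
                         config=cfg, rng=5)
    np.testing.assert_array_equal(p1, p2)


def test_stacking_manifest_records_provenance():
    cfg = TrainConfig(max_epochs=5, patience=2, seed=0)
    train, val, test = _windows(20, 0), _windows(8, 1), _windows(6, 2)
    ens, _ = fit_stacking(ArchitectureSpec("MLP"), 2, "mean", train, val, test,
                          config=cfg, rng=1)
    m = ens.manifest()
    assert m["n_base"] == 2 and m["meta_kind"] == "mean"
    assert len(m["base_seeds"]) == 2
    assert all(len(idx) == train.n for idx in m["bootstrap_indices"])
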