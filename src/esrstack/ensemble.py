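"""Two-stage stacking: bootstrap-trained base forecasters + a meta-combiner.

Stage one trains N_B base models (all of one architecture) on independent
bootstrap resamples of the training windows.  Stage two collects the base
forecasts into an n x M matrix Z and combines them with one of four meta
models:

* mean      z_a = (1/M) sum_i z_i
* median    row-wise sample median (mean of the middle two for even M)
* LASSO     beta_hat = argmin ||y - Z beta||^2 + lambda ||beta||_1,
            lambda picked by fivefold cross-validation on a log-spaced path
* PLSR      partial least squares with J latent components, J picked by
            fivefold cross-validation

Because all bases solve the same task their forecasts are highly collinear;
the regularized combiners (LASSO, PLSR) exist precisely to stay stable under
that multicollinearity.  The meta model is fitted on the base forecasts for
the *validation* split, never the training split, so an overfit base cannot
leak a spuriously good weight into the combiner.  Both regression combiners
carry an intercept (fitted via centering): ESR forecasts live near 0.3-0.9,
not 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from esrstack.basemodels import (
    ArchitectureSpec,
    TrainConfig,
    TrainedModel,
    WindowSet,
    predict,
    train_model,
)

META_KINDS = ("mean", "median", "lasso", "plsr")


@dataclass
class ForecastMatrix:
    """Base forecasts Z (n x M) aligned with observed targets y."""

    Z: np.ndarray
    y: np.ndarray
    model_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.Z.shape[0] != self.y.size:
            raise ValueError("Z rows must align with y")
        if self.Z.shape[1] < 1:
            raise ValueError("need at least one base-model column")
        if not (np.all(np.isfinite(self.Z)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in forecast matrix")
        if not self.model_ids:
            self.model_ids = [f"base_{j}" for j in range(self.Z.shape[1])]


def bootstrap_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws with replacement from 0..n-1 (a standard bagging resample)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.integers(0, n, size=n)


def combine_mean(Z: np.ndarray) -> np.ndarray:
    return np.atleast_2d(np.asarray(Z, dtype=float)).mean(axis=1)


def combine_median(Z: np.ndarray) -> np.ndarray:
    return np.median(np.atleast_2d(np.asarray(Z, dtype=float)), axis=1)


def _cv_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Contiguous blocks after one seeded shuffle."""
    order = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(order, folds)]


@dataclass
class MetaModel:
    """Fitted combiner; ``predict`` maps an (n, M) forecast matrix to forecasts."""

    kind: str
    coef: np.ndarray | None = None       # lasso slopes or PLSR coefficient vector
    intercept: float = 0.0
    lambda_: float | None = None         # chosen LASSO penalty (||.||^2 + lambda ||.||_1 scale)
    n_components: int | None = None      # chosen PLSR J
    cv_curve: list[tuple[float, float]] = field(default_factory=list)  # (grid value, CV MSE)
    _pls: PLSRegression | None = None

    def predict(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.kind == "mean":
            return combine_mean(Z)
        if self.kind == "median":
            return combine_median(Z)
        if self.kind == "lasso":
            return Z @ self.coef + self.intercept
        if self.kind == "plsr":
            return self._pls.predict(Z).ravel()
        raise ValueError(f"unknown meta kind {self.kind!r}")


def _fit_lasso_raw(Z: np.ndarray, y: np.ndarray, lambda_: float) -> tuple[np.ndarray, float]:
    """Solve argmin ||y - Zb||^2 + lambda ||b||_1 with an intercept via centering."""
    n = Z.shape[0]
    z_mean = Z.mean(axis=0)
    y_mean = y.mean()
    Zc = Z - z_mean
    yc = y - y_mean
    if lambda_ <= 0:
        coef, *_ = np.linalg.lstsq(Zc, yc, rcond=None)
    else:
        # sklearn's objective is (1/2n)||y-Zb||^2 + alpha||b||_1
        alpha = lambda_ / (2.0 * n)
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=20000, tol=1e-7)
        with warnings.catch_warnings():
            # duality gaps at this tolerance are ~1e-9 on forecasts of
            # magnitude 1; the residual warning is noise
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Zc, yc)
        coef = model.coef_
    intercept = float(y_mean - z_mean @ coef)
    return np.asarray(coef, dtype=float), intercept


def lambda_path(Z: np.ndarray, y: np.ndarray, n_values: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all slopes zero) down ``decades``."""
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    lam_max = 2.0 * np.max(np.abs(Zc.T @ yc))
    if lam_max <= 0:
        lam_max = 1.0  # degenerate (constant) design; any penalty zeroes slopes
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_values)


def fit_lasso(
    Z: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    folds: int = 5,
    rng: np.random.Generator | int | None = None,
) -> MetaModel:
    """LASSO combiner with the penalty chosen by fivefold cross-validation."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    if Z.shape[0] <= folds:
        raise ValueError(f"need more than {folds} samples for {folds}-fold CV")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if lambda_grid is None:
        lambda_grid = lambda_path(Z, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid < 0):
        raise ValueError("lambda grid must be non-negative")
    fold_idx = _cv_folds(Z.shape[0], folds, rng)
    cv_curve = []
    for lam in lambda_grid:
        errs = []
        for hold in fold_idx:
            mask = np.ones(Z.shape[0], dtype=bool)
            mask[hold] = False
            coef, intercept = _fit_lasso_raw(Z[mask], y[mask], lam)
            pred = Z[hold] @ coef + intercept
            errs.append(np.mean((pred - y[hold]) ** 2))
        cv_curve.append((float(lam), float(np.mean(errs))))
    best_lam = min(cv_curve, key=lambda t: t[1])[0]
    coef, intercept = _fit_lasso_raw(Z, y, best_lam)
    return MetaModel(kind="lasso", coef=coef, intercept=intercept,
                     lambda_=best_lam, cv_curve=cv_curve)


def _fit_pls_raw(Z: np.ndarray, y: np.ndarray, J: int) -> PLSRegression:
    pls = PLSRegression(n_components=J, scale=False)
    pls.fit(Z, y)
    return pls


def fit_plsr(
    Z: np.ndarray,
    y: np.ndarray,
    J_grid: list[int] | None = None,
    folds: int = 5,
    rng: np.random.Generator | int | None = None,
) -> MetaModel:
    """PLSR combiner; latent-component count J chosen by fivefold CV.

    Components are extracted by the classical iterative (NIPALS) algorithm on
    centered data, which for a single response is exact: with J equal to the
    column rank the predictions coincide with least squares.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    n, M = Z.shape
    if n <= folds:
        raise ValueError(f"need more than {folds} samples for {folds}-fold CV")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rank = np.linalg.matrix_rank(Z - Z.mean(axis=0))
    max_J = max(1, min(M, rank))
    if J_grid is None:
        J_grid = list(range(1, max_J + 1))
    else:
        J_grid = sorted(set(int(j) for j in J_grid))
        if any(j < 1 or j > M for j in J_grid):
            raise ValueError("J grid must lie in 1..M")
        if max(J_grid) > max_J:
            warnings.warn(
                f"J grid truncated to rank {max_J} of the forecast matrix", stacklevel=2
            )
            J_grid = [j for j in J_grid if j <= max_J] or [max_J]
    fold_idx = _cv_folds(n, folds, rng)
    cv_curve = []
    for J in J_grid:
        errs = []
        for hold in fold_idx:
            mask = np.ones(n, dtype=bool)
            mask[hold] = False
            J_eff = min(J, np.linalg.matrix_rank(Z[mask] - Z[mask].mean(axis=0)))
            pls = _fit_pls_raw(Z[mask], y[mask], max(1, J_eff))
            pred = pls.predict(Z[hold]).ravel()
            errs.append(np.mean((pred - y[hold]) ** 2))
        cv_curve.append((float(J), float(np.mean(errs))))
    best_J = int(min(cv_curve, key=lambda t: t[1])[0])
    pls = _fit_pls_raw(Z, y, best_J)
    coef = pls.coef_.reshape(-1)
    intercept = float(pls.intercept_.reshape(-1)[0]) if hasattr(pls, "intercept_") else 0.0
    return MetaModel(kind="plsr", coef=coef, intercept=intercept,
                     n_components=best_J, cv_curve=cv_curve, _pls=pls)


def fit_meta(kind: str, Z: np.ndarray, y: np.ndarray,
             rng: np.random.Generator | int | None = None) -> MetaModel:
    if kind == "mean":
        return MetaModel(kind="mean")
    if kind == "median":
        return MetaModel(kind="median")
    if kind == "lasso":
        return fit_lasso(Z, y, rng=rng)
    if kind == "plsr":
        return fit_plsr(Z, y, rng=rng)
    raise ValueError(f"meta kind must be one of {META_KINDS}, got {kind!r}")


@dataclass
class StackedEnsemble:
    """N_B trained bases + fitted meta model, with full seed provenance."""

    bases: list[TrainedModel]
    bootstrap_sets: list[np.ndarray]
    base_seeds: list[int]
    meta: MetaModel
    length_min: float

    @property
    def n_base(self) -> int:
        return len(self.bases)

    def forecast_matrix(self, windows: WindowSet) -> np.ndarray:
        return np.column_stack([predict(b, windows) for b in self.bases])

    def predict(self, windows: WindowSet) -> np.ndarray:
        return self.meta.predict(self.forecast_matrix(windows))

    def manifest(self) -> dict:
        return {
            "n_base": self.n_base,
            "base_kind": self.bases[0].spec.kind if self.bases else None,
            "meta_kind": self.meta.kind,
            "length_min": self.length_min,
            "base_seeds": [int(s) for s in self.base_seeds],
            "bootstrap_indices": [idx.tolist() for idx in self.bootstrap_sets],
            "lambda": self.meta.lambda_,
            "n_components": self.meta.n_components,
            "cv_curve": self.meta.cv_curve,
        }


def train_bases(
    base_spec: ArchitectureSpec,
    n_base: int,
    train: WindowSet,
    val: WindowSet,
    config: TrainConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TrainedModel], list[np.ndarray], list[int]]:
    """Stage one: N_B bases on independent bootstrap resamples of ``train``."""
    if n_base < 1:
        raise ValueError("need at least one base model")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bases, boot_sets, seeds = [], [], []
    for b in range(n_base):
        idx = bootstrap_indices(train.n, rng)
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = TrainConfig(
            max_epochs=config.max_epochs, patience=config.patience,
            initial_lr=config.initial_lr, decay_rate=config.decay_rate,
            decay_steps=config.decay_steps, batch_size=config.batch_size, seed=seed,
        )
        try:
            model = train_model(base_spec, cfg, train.subset(idx), val)
        except Exception as exc:
            raise RuntimeError(f"base model {b} failed to train: {exc}") from exc
        bases.append(model)
        boot_sets.append(idx)
        seeds.append(seed)
    return bases, boot_sets, seeds


def fit_stacking(
    base_spec: ArchitectureSpec,
    n_base: int,
    meta_kind: str,
    train: WindowSet,
    val: WindowSet,
    test: WindowSet,
    config: TrainConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[StackedEnsemble, np.ndarray]:
    """Full two-stage fit; returns the ensemble and its test-split forecasts."""
    config = config or TrainConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bases, boot_sets, seeds = train_bases(base_spec, n_base, train, val, config, rng)
    Z_val = np.column_stack([predict(b, val) for b in bases])
    meta = fit_meta(meta_kind, Z_val, val.y, rng=rng)
    ensemble = StackedEnsemble(
        bases=bases, bootstrap_sets=boot_sets, base_seeds=seeds,
        meta=meta, length_min=train.length_min,
    )
    return ensemble, ensemble.predict(test)


def save_manifest(ensemble: StackedEnsemble, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble.manifest(), fh, indent=1)
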