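"""Error metrics and the repeated-evaluation / sweep protocols.

MAPE = (1/n) sum |(y_i - yhat_i)/y_i| * 100 (%)
RMSE = sqrt((1/n) sum (y_i - yhat_i)^2)

A cohort is split once (seeded shuffle, 194/50/60 proportions) into train /
validation / test subjects; that split stays fixed while D repetitions vary
only the stochastic parts of fitting (weight initialization, minibatch order,
bootstrap resamples).  Each repetition emits one (MAPE, RMSE) record per
model, and reported summaries are means +- SD (ddof=1) over repetitions.
Ensemble entries that share a base family and ensemble size within one
repetition reuse the same trained bases, so the meta-models are compared on
identical first stages.

Two sweeps re-run this protocol along the axes that matter for the study
design: the input window length L (5-20 min in 2.5-min steps) and the
ensemble size N_B (3-10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from esrstack.basemodels import (
    ArchitectureSpec,
    MODEL_KINDS,
    STANDARD_LENGTHS,
    TrainConfig,
    WindowSet,
    make_windows,
    predict,
    train_model,
)
from esrstack.ensemble import META_KINDS, fit_meta, train_bases
from esrstack.synth import SedimentationCurve

#: cohort split proportions of the reference protocol (train/val/test of 304)
SPLIT_REFERENCE = (194, 50, 60)

#: baseline predictors usable anywhere a model kind is accepted
BASELINE_KINDS = ("oracle", "mean_baseline")


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, in percent."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if np.any(y_true == 0):
        raise ValueError("MAPE undefined for zero targets")
    return float(np.mean(np.abs((y_true - y_pred) / y_true)) * 100.0)


def rmse(y_true, y_pred) -> float:
    """Root mean squared error (same units as the targets)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def proportional_split_sizes(n: int, reference=SPLIT_REFERENCE) -> tuple[int, int, int]:
    """Scale the 194/50/60 reference split to a cohort of ``n`` subjects."""
    total = sum(reference)
    train = int(round(n * reference[0] / total))
    val = int(round(n * reference[1] / total))
    test = n - train - val
    if min(train, val, test) < 1:
        raise ValueError(f"cohort of {n} too small to split into three sets")
    return train, val, test


def split_cohort(
    curves: list[SedimentationCurve],
    sizes: tuple[int, int, int] | None = None,
    seed: int = 0,
):
    """Seeded shuffle into (train, val, test) curve lists."""
    n = len(curves)
    sizes = sizes or proportional_split_sizes(n)
    if sum(sizes) != n:
        raise ValueError(f"split sizes {sizes} do not sum to cohort size {n}")
    order = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    pick = lambda idx: [curves[i] for i in idx]
    return pick(order[:a]), pick(order[a:b]), pick(order[b:])


@dataclass(frozen=True)
class EvalModel:
    """One entry of the evaluation roster.

    ``n_base`` None -> a single model trained on the whole training split;
    otherwise a stacked ensemble of ``n_base`` bootstrap bases combined by
    ``meta_kind``.
    """

    base_kind: str
    n_base: int | None = None
    meta_kind: str | None = None

    def __post_init__(self) -> None:
        if self.base_kind not in MODEL_KINDS + BASELINE_KINDS:
            raise ValueError(f"unknown model kind {self.base_kind!r}")
        if (self.n_base is None) != (self.meta_kind is None):
            raise ValueError("ensemble entries need both n_base and meta_kind")
        if self.meta_kind is not None and self.meta_kind not in META_KINDS:
            raise ValueError(f"unknown meta kind {self.meta_kind!r}")
        if self.n_base is not None and self.n_base < 1:
            raise ValueError("n_base must be >= 1")

    @property
    def model_id(self) -> str:
        if self.meta_kind is None:
            return self.base_kind
        pretty = {"mean": "Mean", "median": "Median", "lasso": "LASSO", "plsr": "PLSR"}
        return f"{self.base_kind}-{pretty[self.meta_kind]}"


def default_roster(n_base: int = 8) -> list[EvalModel]:
    """The headline 11-model comparison: 3 individual DNNs + 2x4 ensembles."""
    roster = [EvalModel(k) for k in MODEL_KINDS]
    for base in ("LSTM", "GRU"):
        for meta in META_KINDS:
            roster.append(EvalModel(base, n_base=n_base, meta_kind=meta))
    return roster


def _predict_baseline(kind: str, train: WindowSet, test: WindowSet) -> np.ndarray:
    if kind == "oracle":
        return test.y.copy()
    if kind == "mean_baseline":
        return np.full(test.n, train.y.mean())
    raise ValueError(kind)


def _one_repetition(
    models: list[EvalModel],
    train: WindowSet,
    val: WindowSet,
    test: WindowSet,
    config: TrainConfig,
    rep_seed: int,
) -> dict[str, np.ndarray]:
    """Train/fit every roster entry once; returns model_id -> test forecasts."""
    rng = np.random.default_rng(rep_seed)
    preds: dict[str, np.ndarray] = {}
    singles = sorted({m.base_kind for m in models if m.n_base is None and m.base_kind in MODEL_KINDS})
    ens_groups = sorted({(m.base_kind, m.n_base) for m in models if m.n_base is not None})
    for kind in singles:
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = TrainConfig(
            max_epochs=config.max_epochs, patience=config.patience,
            initial_lr=config.initial_lr, decay_rate=config.decay_rate,
            decay_steps=config.decay_steps, batch_size=config.batch_size, seed=seed,
        )
        model = train_model(ArchitectureSpec(kind), cfg, train, val)
        preds[kind] = predict(model, test)
    for m in models:
        if m.base_kind in BASELINE_KINDS:
            preds[m.model_id] = _predict_baseline(m.base_kind, train, test)
    for base_kind, n_base in ens_groups:
        bases, _, _ = train_bases(
            ArchitectureSpec(base_kind), n_base, train, val, config, rng
        )
        Z_val = np.column_stack([predict(b, val) for b in bases])
        Z_test = np.column_stack([predict(b, test) for b in bases])
        for m in models:
            if m.base_kind == base_kind and m.n_base == n_base:
                meta = fit_meta(m.meta_kind, Z_val, val.y, rng=rng)
                preds[m.model_id] = meta.predict(Z_test)
    return preds


def repeated_eval(
    curves: list[SedimentationCurve],
    models: list[EvalModel],
    length_min: float = 15.0,
    D: int = 30,
    master_seed: int = 0,
    split_sizes: tuple[int, int, int] | None = None,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """D repetitions of the full fit/evaluate cycle at one operating point.

    Returns tidy records (model_id, repetition, mape, rmse).  The split is
    derived from the master seed and held fixed; repetition r reseeds only
    initialization, batching and bootstraps.
    """
    if D < 1:
        raise ValueError("need at least one repetition")
    config = config or TrainConfig()
    tr_c, va_c, te_c = split_cohort(curves, split_sizes, seed=master_seed)
    train = make_windows(tr_c, length_min, allow_any_length=True)
    val = make_windows(va_c, length_min, allow_any_length=True)
    test = make_windows(te_c, length_min, allow_any_length=True)
    rep_seeds = np.random.SeedSequence(master_seed).generate_state(D) % (2**31 - 1)
    rows = []
    for r in range(1, D + 1):
        preds = _one_repetition(models, train, val, test, config, int(rep_seeds[r - 1]))
        for m in models:
            yhat = preds[m.model_id]
            rows.append(
                {
                    "model_id": m.model_id,
                    "repetition": r,
                    "mape": mape(test.y, yhat),
                    "rmse": rmse(test.y, yhat),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SweepTable:
    """Per-cell mean +- SD of MAPE/RMSE along one experimental axis."""

    axis: str                # "length_min" or "n_base"
    records: pd.DataFrame    # tidy per-repetition records with the axis column
    D: int

    @property
    def summary(self) -> pd.DataFrame:
        g = self.records.groupby([self.axis, "model_id"])
        out = g.agg(
            mean_mape=("mape", "mean"),
            sd_mape=("mape", lambda s: s.std(ddof=1)),
            mean_rmse=("rmse", "mean"),
            sd_rmse=("rmse", lambda s: s.std(ddof=1)),
        ).reset_index()
        return out


def sequence_length_sweep(
    curves: list[SedimentationCurve],
    models: list[EvalModel],
    lengths: tuple[float, ...] = STANDARD_LENGTHS,
    D: int = 30,
    master_seed: int = 0,
    split_sizes: tuple[int, int, int] | None = None,
    config: TrainConfig | None = None,
) -> SweepTable:
    """Re-window and re-evaluate at each input length L."""
    frames = []
    for L in lengths:
        rec = repeated_eval(curves, models, L, D, master_seed, split_sizes, config)
        rec.insert(0, "length_min", L)
        frames.append(rec)
    return SweepTable(axis="length_min", records=pd.concat(frames, ignore_index=True), D=D)


def ensemble_size_sweep(
    curves: list[SedimentationCurve],
    base_kind: str,
    meta_kinds: tuple[str, ...] = META_KINDS,
    n_base_range: tuple[int, ...] = tuple(range(3, 11)),
    length_min: float = 15.0,
    D: int = 30,
    master_seed: int = 0,
    split_sizes: tuple[int, int, int] | None = None,
    config: TrainConfig | None = None,
) -> SweepTable:
    """Vary the number of bootstrap bases N_B at a fixed window length."""
    frames = []
    for n_b in n_base_range:
        models = [EvalModel(base_kind, n_base=n_b, meta_kind=mk) for mk in meta_kinds]
        rec = repeated_eval(curves, models, length_min, D, master_seed, split_sizes, config)
        rec.insert(0, "n_base", n_b)
        frames.append(rec)
    return SweepTable(axis="n_base", records=pd.concat(frames, ignore_index=True), D=D)
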