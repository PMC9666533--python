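"""Statistical model comparison: Friedman ranks, Nemenyi CD, Bland-Altman.

The Friedman test ranks the k models within each of the D repetitions
(rank 1 = lowest error; ties get average ranks) and tests whether the mean
ranks could be equal.  When it rejects, the Nemenyi post-hoc procedure calls
a pair of models significantly different when their mean ranks differ by at
least the critical distance

    CD = q_alpha * sqrt(k (k+1) / (6 D)),

with q_alpha the studentized-range critical value (infinite df) divided by
sqrt(2).  Bland-Altman analysis quantifies agreement between predicted and
measured ESR values as a bias (mean difference) with 95% limits of agreement
(bias +- 1.96 SD of the differences).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: studentized-range critical values (infinite df) divided by sqrt(2),
#: indexed by number of models k = 2..15; the standard Nemenyi table.
Q_ALPHA_TABLE = {
    0.05: {
        2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850, 7: 2.949, 8: 3.031,
        9: 3.102, 10: 3.164, 11: 3.219, 12: 3.268, 13: 3.313, 14: 3.354, 15: 3.391,
    },
    0.10: {
        2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589, 7: 2.693, 8: 2.780,
        9: 2.855, 10: 2.920, 11: 2.978, 12: 3.030, 13: 3.077, 14: 3.120, 15: 3.158,
    },
}

#: above this many distinct within-row permutations the permutation p-value
#: falls back from exhaustive enumeration to seeded Monte Carlo
_EXACT_PERM_LIMIT = 300_000


def _rank_rows(errors: np.ndarray) -> np.ndarray:
    """Within-row ranks, ascending (best = 1), average ranks on ties."""
    return np.apply_along_axis(stats.rankdata, 1, errors)


def friedman(
    errors,
    p_method: str = "chi2",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Friedman test on a D x k error matrix (rows = repetitions/datasets).

    Returns (statistic, p_value, mean_ranks).  ``p_method``:

    * ``"chi2"`` — classical chi-square approximation with tie correction
      (agrees with scipy.stats.friedmanchisquare);
    * ``"f"`` — Iman-Davenport F variant of the same statistic;
    * ``"permutation"`` — within-row permutation null, enumerated exhaustively
      when feasible and otherwise estimated by seeded Monte Carlo.  Preferred
      at very small D where the chi-square approximation is poor.
    """
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    D, k = errors.shape
    if D < 2 or k < 2:
        raise ValueError("need at least 2 repetitions and 2 models")
    if p_method not in ("chi2", "f", "permutation"):
        raise ValueError("p_method must be 'chi2', 'f' or 'permutation'")
    ranks = _rank_rows(errors)
    mean_ranks = ranks.mean(axis=0)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums**2))
    # tie correction, as in the classical tie-adjusted statistic
    ties = 0.0
    for row in errors:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (k * (k * k - 1) * D)
    if c <= 0:  # every row fully tied
        return 0.0, 1.0, mean_ranks
    statistic = (12.0 / (k * D * (k + 1)) * ssbn - 3.0 * D * (k + 1)) / c
    if p_method == "chi2":
        p = float(stats.chi2.sf(statistic, k - 1))
    elif p_method == "f":
        denom = D * (k - 1) - statistic
        if denom <= 0:
            p = 0.0
        else:
            f_stat = (D - 1) * statistic / denom
            p = float(stats.f.sf(f_stat, k - 1, (k - 1) * (D - 1)))
    elif p_method == "permutation":
        p = _permutation_p(ranks, ssbn, n_permutations, seed)
    else:
        raise ValueError("p_method must be 'chi2', 'f' or 'permutation'")
    return float(statistic), p, mean_ranks


def _permutation_p(ranks: np.ndarray, ssbn_obs: float, n_permutations: int, seed: int) -> float:
    """P(sum of squared column rank sums >= observed) under within-row shuffles.

    The tie pattern of each row is permutation-invariant, so comparing the
    un-normalized ssbn is equivalent to comparing the tie-corrected statistic.
    """
    D, k = ranks.shape
    n_exact = math.factorial(k) ** D
    tol = 1e-9
    if n_exact <= _EXACT_PERM_LIMIT:
        row_perms = [
            {tuple(p) for p in itertools.permutations(row)} for row in ranks
        ]
        hits = total = 0
        for combo in itertools.product(*[sorted(s) for s in row_perms]):
            arr = np.array(combo)
            ssbn = float(np.sum(arr.sum(axis=0) ** 2))
            hits += ssbn >= ssbn_obs - tol
            total += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = np.array([rng.permutation(row) for row in ranks])
        ssbn = float(np.sum(perm.sum(axis=0) ** 2))
        hits += ssbn >= ssbn_obs - tol
    return (hits + 1) / (n_permutations + 1)


@dataclass
class NemenyiResult:
    cd: float
    alpha: float
    q_alpha: float
    mean_ranks: np.ndarray
    model_ids: list[str]
    pairwise: np.ndarray  # k x k boolean, True = significantly different


def nemenyi_cd(k: int, D: int, alpha: float = 0.05) -> float:
    """Critical distance CD = q_alpha * sqrt(k(k+1)/(6D))."""
    table = Q_ALPHA_TABLE.get(alpha)
    if table is None:
        raise ValueError(f"alpha must be one of {sorted(Q_ALPHA_TABLE)}")
    if k not in table:
        raise ValueError(f"k={k} outside the embedded table (k = 2..{max(table)})")
    if D < 1:
        raise ValueError("D must be >= 1")
    return table[k] * math.sqrt(k * (k + 1) / (6.0 * D))


def nemenyi_pairs(mean_ranks, cd: float) -> np.ndarray:
    """Pair (i, j) is significant iff |mean_rank_i - mean_rank_j| >= cd."""
    if cd <= 0:
        raise ValueError("cd must be positive")
    r = np.asarray(mean_ranks, dtype=float)
    diff = np.abs(r[:, None] - r[None, :])
    sig = diff >= cd
    np.fill_diagonal(sig, False)
    return sig


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray        # (pred + true) / 2 per sample
    differences: np.ndarray  # pred - true per sample

    @property
    def coverage(self) -> float:
        """Fraction of differences inside the limits of agreement."""
        inside = (self.differences >= self.loa_low) & (self.differences <= self.loa_high)
        return float(inside.mean())


def bland_altman(y_true, y_pred) -> BlandAltmanResult:
    """Agreement analysis; differences are predicted minus actual."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = y_pred - y_true
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        means=(y_pred + y_true) / 2.0,
        differences=d,
    )


@dataclass
class MetricComparison:
    metric: str
    statistic: float
    p_value: float
    mean_ranks: pd.Series          # indexed by model_id, sorted best first
    cd: float | None
    pairwise: pd.DataFrame | None  # boolean significance matrix
    groups: list[list[str]]        # bars of mutually non-significant models


@dataclass
class ComparisonReport:
    alpha: float
    D: int
    k: int
    metrics: dict[str, MetricComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mc in self.metrics.values():
            for model_id, rank in mc.mean_ranks.items():
                rows.append(
                    {
                        "metric": mc.metric,
                        "model_id": model_id,
                        "mean_rank": rank,
                        "friedman_statistic": mc.statistic,
                        "friedman_p": mc.p_value,
                        "cd": mc.cd,
                    }
                )
        return pd.DataFrame(rows)


def _rank_groups(sorted_ranks: pd.Series, cd: float) -> list[list[str]]:
    """Maximal runs of rank-adjacent models whose rank spread is below CD."""
    ids = list(sorted_ranks.index)
    vals = sorted_ranks.to_numpy()
    groups = []
    for i in range(len(ids)):
        j = i
        while j + 1 < len(ids) and vals[j + 1] - vals[i] < cd:
            j += 1
        if j > i:
            groups.append(ids[i : j + 1])
    # keep only maximal bars
    maximal = [g for g in groups if not any(set(g) < set(h) for h in groups)]
    out = []
    for g in maximal:
        if g not in out:
            out.append(g)
    return out


def full_comparison(
    records: pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = ("mape", "rmse"),
    p_method: str = "chi2",
) -> ComparisonReport:
    """Friedman + (if significant) Nemenyi on tidy repeated-eval records.

    ``records`` must hold columns model_id, repetition and one column per
    metric, with every (model, repetition) cell present.
    """
    results: dict[str, MetricComparison] = {}
    D = k = 0
    for metric in metrics:
        table = records.pivot(index="repetition", columns="model_id", values=metric)
        if table.isna().any().any():
            missing = [
                f"({r}, {c})" for c in table.columns for r in table.index[table[c].isna()]
            ]
            raise ValueError(f"incomplete comparison table; missing cells: {missing[:5]}")
        D, k = table.shape
        stat, p, mean_ranks = friedman(table.to_numpy(), p_method=p_method)
        ranks = pd.Series(mean_ranks, index=table.columns).sort_values()
        if p < alpha:
            cd = nemenyi_cd(k, D, alpha)
            sig = nemenyi_pairs(ranks.to_numpy(), cd)
            pairwise = pd.DataFrame(sig, index=ranks.index, columns=ranks.index)
            groups = _rank_groups(ranks, cd)
        else:
            cd, pairwise, groups = None, None, []
        results[metric] = MetricComparison(
            metric=metric, statistic=stat, p_value=p,
            mean_ranks=ranks, cd=cd, pairwise=pairwise, groups=groups,
        )
    return ComparisonReport(alpha=alpha, D=D, k=k, metrics=results)
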