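"""Descriptive responder-group comparisons.

Continuous measures are compared with the Kruskal-Wallis test across
unpaired groups and the Wilcoxon signed rank test for paired
(within-physician) contrasts; categorical measures use the Fisher exact
test. No multiple-testing correction is applied. Comparisons use each
physician's most recent invited wave.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, ValidationError

TEST_FISHER = "fisher"
TEST_KRUSKAL_WALLIS = "kruskal_wallis"
TEST_WILCOXON_SIGNED_RANK = "wilcoxon_signed_rank"

#: Exact enumeration is used for 2xC tables with at most this many columns.
MAX_EXACT_FISHER_COLS = 3


@dataclass
class ComparisonRow:
    measure: str
    test: str
    p_value: float
    degenerate: bool = False
    summaries: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _table_log_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a 2xC table."""
    col = table.sum(axis=0)
    n = int(table.sum())
    r0 = int(table[0].sum())
    # -log C(N, r0) plus sum_j log C(c_j, a_j)
    lp = -(math.lgamma(n + 1) - math.lgamma(r0 + 1) - math.lgamma(n - r0 + 1))
    for a, c in zip(table[0], col):
        lp += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
    return lp


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for a 2xC table by full enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise DomainError("exact enumeration implemented for 2-row tables")
    col = table.sum(axis=0)
    r0 = int(table[0].sum())
    obs_lp = _table_log_prob(table)
    total = 0.0
    p = 0.0
    ranges = [range(int(c) + 1) for c in col]
    for a in itertools.product(*ranges):
        if sum(a) != r0:
            continue
        cand = np.array([list(a), (col - np.array(a)).tolist()])
        lp = _table_log_prob(cand)
        prob = math.exp(lp)
        total += prob
        if lp <= obs_lp + 1e-10:
            p += prob
    # margins fully determine the sample space; total ~ 1
    return min(p / total, 1.0)


def fisher_monte_carlo(table: np.ndarray, n_mc: int = 20000, seed: int = 0) -> float:
    """Seeded Monte Carlo Fisher test for tables larger than 2xC."""
    table = np.asarray(table, dtype=int)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    obs_lp = _log_prob_rxc(table)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        cand = np.zeros_like(table)
        np.add.at(cand, (rows, perm), 1)
        if _log_prob_rxc(cand) <= obs_lp + 1e-10:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def _log_prob_rxc(table: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(math.lgamma(x + 1) for x in r)
        + sum(math.lgamma(x + 1) for x in c)
        - math.lgamma(n + 1)
        - sum(math.lgamma(x + 1) for x in table.ravel())
    )
    return lp


def fisher_test(table: np.ndarray, seed: int = 0) -> float:
    """Two-sided Fisher exact test; Monte Carlo beyond 2x3."""
    table = np.asarray(table, dtype=int)
    if min(table.shape) < 2:
        return float("nan")
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    if table.shape[0] == 2 and table.shape[1] <= MAX_EXACT_FISHER_COLS:
        return fisher_exact_2xc(table)
    if table.shape[1] == 2 and table.shape[0] <= MAX_EXACT_FISHER_COLS:
        return fisher_exact_2xc(table.T)
    return fisher_monte_carlo(table, seed=seed)


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _count_pct(x: pd.Series) -> str:
    counts = x.value_counts().sort_index()
    n = len(x)
    return "; ".join(f"{lvl}: {c} ({100.0 * c / n:.0f}%)" for lvl, c in counts.items())


def _latest_wave_rows(features: pd.DataFrame) -> pd.DataFrame:
    idx = features.groupby("physician_id")["wave"].idxmax()
    return features.loc[idx]


def compare_groups(
    features: pd.DataFrame,
    categories: pd.Series,
    seed: int = 0,
) -> List[ComparisonRow]:
    """Compare measures across responder groups (one row per measure).

    ``features`` has one row per (physician, wave); the most recent
    invited wave per physician is used. ``categories`` maps
    physician_id -> responder category. Continuous measures use
    Kruskal-Wallis, categorical measures Fisher exact. Empty groups are
    dropped with a warning; fewer than 2 nonempty groups is an error.
    """
    latest = _latest_wave_rows(features).set_index("physician_id")
    latest = latest.join(categories.rename("category"), how="inner")

    group_sizes = latest["category"].value_counts()
    empty = [g for g in categories.unique() if group_sizes.get(g, 0) == 0]
    if empty:
        warnings.warn(f"dropping empty groups: {empty}")
    groups = [g for g in group_sizes.index if group_sizes[g] > 0]
    if len(groups) < 2:
        raise DomainError("need at least 2 nonempty groups to compare")

    rows: List[ComparisonRow] = []
    for colname in latest.columns:
        if colname in ("category", "wave"):
            continue
        col = latest[colname]
        by_group = {g: col[latest["category"] == g] for g in groups}
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            samples = [v.to_numpy(dtype=float) for v in by_group.values()]
            summaries = {g: _median_iqr(v.to_numpy(float)) for g, v in by_group.items()}
            if np.unique(np.concatenate(samples)).size < 2:
                rows.append(
                    ComparisonRow(colname, TEST_KRUSKAL_WALLIS, float("nan"),
                                  degenerate=True, summaries=summaries)
                )
                continue
            try:
                p = float(stats.kruskal(*samples)[1])
                rows.append(ComparisonRow(colname, TEST_KRUSKAL_WALLIS, p,
                                          summaries=summaries))
            except ValueError:
                rows.append(
                    ComparisonRow(colname, TEST_KRUSKAL_WALLIS, float("nan"),
                                  degenerate=True, summaries=summaries)
                )
        else:
            table = pd.crosstab(latest["category"], col).reindex(groups).fillna(0)
            summaries = {g: _count_pct(v) for g, v in by_group.items()}
            if table.shape[1] < 2:
                rows.append(ComparisonRow(colname, TEST_FISHER, float("nan"),
                                          degenerate=True, summaries=summaries))
                continue
            p = fisher_test(table.to_numpy(), seed=seed)
            rows.append(ComparisonRow(colname, TEST_FISHER, p, summaries=summaries))
    return rows


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> ComparisonRow:
    """Two-sided Wilcoxon signed rank on paired vectors, zeros dropped.

    Exact sign-permutation p at n <= 12 (handles tied magnitudes), the
    usual exact/normal machinery otherwise. All-zero differences are
    flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise DomainError("paired vectors must have equal length >= 2")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        return ComparisonRow("", TEST_WILCOXON_SIGNED_RANK, float("nan"),
                             degenerate=True)
    if len(nz) <= 12:
        method = stats.PermutationMethod(n_resamples=2 ** len(nz))
    else:
        method = "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return ComparisonRow("", TEST_WILCOXON_SIGNED_RANK, float(res.pvalue))


def compare_paired_years(
    response_year: pd.DataFrame, nonresponse_year: pd.DataFrame
) -> List[ComparisonRow]:
    """Paired response-year vs nonresponse-year comparison per measure.

    Both frames must be aligned row-wise (one row per physician) with
    identical numeric columns.
    """
    if list(response_year.columns) != list(nonresponse_year.columns):
        raise ValidationError("paired frames must share identical columns")
    rows = []
    for colname in response_year.columns:
        if not pd.api.types.is_numeric_dtype(response_year[colname]):
            continue
        row = wilcoxon_signed_rank(
            response_year[colname].to_numpy(float),
            nonresponse_year[colname].to_numpy(float),
        )
        row.measure = colname
        row.summaries = {
            "response_year": _median_iqr(response_year[colname].to_numpy(float)),
            "nonresponse_year": _median_iqr(nonresponse_year[colname].to_numpy(float)),
        }
        rows.append(row)
    return rows


def rows_to_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Flatten comparison rows into a table for CSV export."""
    return pd.DataFrame(
        {
            "measure": [r.measure for r in rows],
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
            "degenerate": [r.degenerate for r in rows],
            "summary": ["; ".join(f"{k}: {v}" for k, v in r.summaries.items())
                         for r in rows],
        }
    )
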