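"""Responsiveness: detecting clinical change over the postoperative course.

Surgical-group scores at diagnosis (T0) and 1, 3 and 6 months after
surgery (T1, T3, T6) are compared pairwise with the Wilcoxon signed-rank
test (complete-case pairing), compared across the four age groups with the
Kruskal-Wallis test at each timepoint, and summarized as median (IQR) per
timepoint.  Demographic 2 x k contingency tables (sex, affected limb) are
compared with Pearson's chi-squared test.

The Wilcoxon test is authored here because the exact small-sample null
distribution must accommodate midrank ties: zero differences are discarded
(Wilcoxon's original rule), absolute differences receive midranks, and for
10 or fewer — in general ``n_used`` <= 15 — informative pairs the two-sided
p-value is obtained by enumerating all 2^n sign assignments of the observed
ranks; beyond that a normal approximation with the standard tie correction
is used.  Tests are two-sided throughout, and the multiple pairwise
timepoint comparisons are reported uncorrected (a Holm adjustment is
available as an option and off by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

EXACT_WILCOXON_MAX_N = 15


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired signed-rank comparison of two timepoints."""

    statistic: Optional[float]  # W+ (sum of positive-difference ranks)
    p_value: float
    n_used: int  # informative (non-zero-difference) pairs
    method: str  # "exact" | "normal-approximation" | "no-change"


@dataclass(frozen=True)
class GroupComparisonResult:
    """Kruskal-Wallis comparison of a score across groups."""

    grouping: str
    h_statistic: float
    df: int
    p_value: float
    group_sizes: Tuple[int, ...]


def wilcoxon_signed_rank(
    before: Sequence[float], after: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired scores.

    Zero differences are discarded; ties among |differences| get
    midranks.  Exact enumeration of the 2^n sign assignments is used for
    n_used <= 15, a tie-corrected normal approximation above.  If every
    difference is zero the result is "no change": p = 1 with an
    undefined statistic.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be 1-d vectors of equal length")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=None, p_value=1.0, n_used=0, method="no-change")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        # all 2^n sign assignments of the observed ranks
        signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
        dist = signs @ ranks
        mu = ranks.sum() / 2.0
        p_low = float((dist <= w_plus + 1e-9).mean())
        p_high = float((dist >= w_plus - 1e-9).mean())
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float((counts**3 - counts).sum()) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            raise DegenerateInputError("zero variance in signed-rank statistic")
        # continuity-corrected z (the statistic moves on a half-integer grid)
        z = max(abs(w_plus - mu) - 0.5, 0.0) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(z))
        method = "normal-approximation"
    return WilcoxonResult(statistic=w_plus, p_value=min(p, 1.0), n_used=n, method=method)


def kruskal_wallis(
    groups: Sequence[Sequence[float]], grouping: str = "age_group"
) -> GroupComparisonResult:
    """Kruskal-Wallis rank test across 2 or more groups (tie-corrected H)."""
    if len(groups) < 2:
        raise DegenerateInputError("Kruskal-Wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DegenerateInputError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return GroupComparisonResult(
        grouping=grouping,
        h_statistic=float(h),
        df=df,
        p_value=float(p),
        group_sizes=tuple(a.size for a in arrays),
    )


def chi_square_independence(table) -> Tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Returns (statistic, df, p_value) for an r x k table of counts.
    """
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-d")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("contingency table must hold non-negative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return (float(res.statistic), int(res.dof), float(res.pvalue))


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def paired_timepoint_tests(
    scores: pd.DataFrame,
    score_columns: Sequence[str],
    timepoints: Sequence[str] = ("T0", "T1", "T3", "T6"),
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise Wilcoxon comparisons of timepoints, per score column.

    ``scores`` is tidy (one row per subject x timepoint, with
    ``subject_id`` and ``timepoint`` columns).  Pairs are complete-case:
    only subjects observed at both timepoints enter a comparison.
    Returns one row per (score, timepoint pair) with the statistic,
    p-value and number of pairs; with ``holm`` the p-values are adjusted
    within each score's family of pairwise tests.
    """
    present = [t for t in timepoints if (scores["timepoint"] == t).any()]
    rows = []
    for col in score_columns:
        wide = scores.pivot(index="subject_id", columns="timepoint", values=col)
        family: List[Tuple[int, float]] = []
        for t_a, t_b in itertools.combinations(present, 2):
            pair = wide[[t_a, t_b]].dropna()
            res = wilcoxon_signed_rank(pair[t_a], pair[t_b])
            rows.append(
                {
                    "score": col,
                    "from": t_a,
                    "to": t_b,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_pairs": len(pair),
                    "method": res.method,
                }
            )
            family.append((len(rows) - 1, res.p_value))
        if holm and family:
            adj = holm_adjust([p for _, p in family])
            for (idx, _), p_adj in zip(family, adj):
                rows[idx]["p_holm"] = p_adj
    return pd.DataFrame(rows)


def age_group_tests(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    score_columns: Sequence[str],
    timepoints: Sequence[str] = ("T0", "T1", "T3", "T6"),
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of each score across age groups per timepoint."""
    merged = scores.merge(metadata[["subject_id", "age_group"]], on="subject_id")
    rows = []
    for t in timepoints:
        at_t = merged[merged["timepoint"] == t]
        if at_t.empty:
            continue
        groups_present = sorted(at_t["age_group"].unique())
        for col in score_columns:
            samples = [
                at_t.loc[at_t["age_group"] == g, col].to_numpy()
                for g in groups_present
            ]
            res = kruskal_wallis(samples)
            rows.append(
                {
                    "timepoint": t,
                    "score": col,
                    "h_statistic": res.h_statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "group_sizes": res.group_sizes,
                }
            )
    return pd.DataFrame(rows)


def median_iqr_table(
    scores: pd.DataFrame,
    score_columns: Sequence[str],
    timepoints: Sequence[str] = ("T0", "T1", "T3", "T6"),
) -> pd.DataFrame:
    """Median and interquartile range per score per timepoint (complete-case).

    One row per (timepoint, score) with median, q1, q3 and n.
    """
    rows = []
    for t in timepoints:
        at_t = scores[scores["timepoint"] == t]
        if at_t.empty:
            raise DegenerateInputError(f"no sheets at timepoint {t}")
        for col in score_columns:
            vals = at_t[col].dropna().to_numpy()
            if vals.size == 0:
                raise DegenerateInputError(f"no defined {col} scores at {t}")
            rows.append(
                {
                    "timepoint": t,
                    "score": col,
                    "median": float(np.median(vals)),
                    "q1": float(np.percentile(vals, 25)),
                    "q3": float(np.percentile(vals, 75)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
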