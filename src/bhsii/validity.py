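"""Construct validity: ROC discrimination and domain correlations.

The instrument's ability to separate healthy dogs from dogs with cranial
cruciate ligament rupture is quantified with an empirical ROC analysis on
the normalized total score (low score = diseased).  The AUC is computed as
the pairwise Mann-Whitney estimator (ties count one half), which equals
the trapezoidal area under the empirical ROC curve.  Sensitivity and
specificity at the reported threshold carry exact Clopper-Pearson 95%
confidence intervals.

Convergent validity between domains, sections and total uses Spearman's
rank correlation with the British Medical Journal qualitative banding of
|r_s|: 0-0.19 very weak, 0.2-0.39 weak, 0.40-0.59 moderate, 0.6-0.79
strong, 0.8-1 very strong.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

AUC_THRESHOLD = 0.7

_BANDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (1.0 + 1e-12, "very strong"),
)


def correlation_band(r: float) -> str:
    """Qualitative label for |r| per the BMJ cuts."""
    a = abs(r)
    if math.isnan(a) or a > 1 + 1e-9:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    for cut, label in _BANDS:
        if a < cut:
            return label
    return "very strong"


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC discrimination between diseased and healthy scores."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    sensitivity_ci: Tuple[float, float]
    specificity_ci: Tuple[float, float]
    n_diseased: int
    n_healthy: int
    #: (lower, upper] score interval of diseased dogs when the groups are
    #: perfectly separable; None otherwise.
    separating_interval: Optional[Tuple[float, float]]

    @property
    def acceptable_accuracy(self) -> bool:
        return self.auc > AUC_THRESHOLD


@dataclass(frozen=True)
class CorrelationCell:
    """One Spearman correlation with its p-value and qualitative band."""

    r_s: float
    p_value: float
    band: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def pairwise_auc(diseased: np.ndarray, healthy: np.ndarray) -> float:
    """Mann-Whitney AUC: P(healthy > diseased) with ties counting 1/2."""
    d = diseased[:, None]
    h = healthy[None, :]
    wins = (h > d).sum() + 0.5 * (h == d).sum()
    return float(wins) / (diseased.size * healthy.size)


def clopper_pearson_ci(
    successes: int, n: int, confidence: float = 0.95
) -> Tuple[float, float]:
    """Exact two-sided binomial confidence interval via Beta quantiles.

    The boundary cases reduce to the closed forms
    lower = (alpha/2)**(1/n) when successes == n and
    upper = 1 - (alpha/2)**(1/n) when successes == 0.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return (lower, upper)


def roc_analysis(
    diseased_scores: Sequence[float],
    healthy_scores: Sequence[float],
    confidence: float = 0.95,
) -> RocResult:
    """ROC analysis of a well-being score (lower score = diseased).

    When the two score distributions do not overlap, the reported
    threshold is the maximal diseased score and ``separating_interval``
    is the (min, max] range of diseased scores, which then classifies
    with 100% sensitivity and specificity.  With overlap, the
    Youden-optimal threshold (maximizing sensitivity + specificity for
    the rule "diseased if score <= threshold") is reported instead.

    The score orientation is fixed by the instrument's semantics
    (0 = severe, 100 = healthy); feeding reversed groups yields
    AUC < 0.5 and a warning, not an auto-flip.
    """
    diseased = np.asarray(diseased_scores, dtype=float)
    healthy = np.asarray(healthy_scores, dtype=float)
    if diseased.size == 0 or healthy.size == 0:
        raise DegenerateInputError("both groups must be non-empty for ROC analysis")
    auc = pairwise_auc(diseased, healthy)
    if auc < 0.5:
        warnings.warn(
            "AUC < 0.5: the diseased group scores above the healthy group; "
            "check the group orientation (low score = diseased)",
            stacklevel=2,
        )

    separable = diseased.max() < healthy.min()
    if separable:
        threshold = float(diseased.max())
        interval: Optional[Tuple[float, float]] = (
            float(diseased.min()),
            float(diseased.max()),
        )
    else:
        interval = None
        candidates = np.unique(np.concatenate([diseased, healthy]))
        best_t, best_j = candidates[0], -np.inf
        for t in candidates:
            sens = float((diseased <= t).mean())
            spec = float((healthy > t).mean())
            j = sens + spec - 1.0
            if j > best_j:
                best_j, best_t = j, t
        threshold = float(best_t)

    tp = int((diseased <= threshold).sum())
    tn = int((healthy > threshold).sum())
    sens = tp / diseased.size
    spec = tn / healthy.size
    return RocResult(
        auc=auc,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=clopper_pearson_ci(tp, diseased.size, confidence),
        specificity_ci=clopper_pearson_ci(tn, healthy.size, confidence),
        n_diseased=int(diseased.size),
        n_healthy=int(healthy.size),
        separating_interval=interval,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p-value for Spearman's r (small n).

    Permutes one rank vector over all n! orderings; only the cross term
    sum(rx_perm * ry) varies, so the correlation for every permutation is
    an affine function of a dot product (chunked for memory).
    """
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std(ddof=0)
    sy = ry.std(ddof=0)
    mean = (n + 1) / 2.0
    count = 0
    total = 0
    chunk: list = []
    threshold = abs(r_obs) - 1e-12

    def _flush(chunk_perms: list) -> int:
        perms = np.array(chunk_perms)
        cross = rx[perms] @ ry / n
        r = (cross - mean * mean) / (sx * sy)
        return int((np.abs(r) >= threshold).sum())

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 100_000:
            count += _flush(chunk)
            chunk = []
    if chunk:
        count += _flush(chunk)
    return count / total


def spearman_cell(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> CorrelationCell:
    """Spearman correlation of two score vectors with banding.

    r_s is the Pearson correlation of midranks (average ranks on ties);
    the two-sided p-value uses the t approximation, or exact permutation
    enumeration when ``exact`` is set (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise DegenerateInputError("Spearman correlation requires >= 4 paired scores")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant column: correlation undefined")
    r, p = stats.spearmanr(x, y)
    r = float(r)
    if exact:
        if x.size > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        p = _spearman_exact_p(x, y, r)
    return CorrelationCell(r_s=r, p_value=float(p), band=correlation_band(r))


def spearman_matrix(score_table: pd.DataFrame) -> Dict[str, Dict[str, CorrelationCell]]:
    """Pairwise Spearman correlations between score columns at one timepoint.

    ``score_table`` holds one row per subject and one column per score
    (e.g. P, S, F, V, M, OQ, CR, total).  Diagonal cells are included
    (r_s = 1).  A constant column yields ``None`` cells for every pair
    involving it (undefined correlation) rather than failing the whole
    matrix.
    """
    if len(score_table) < 4:
        raise DegenerateInputError("Spearman matrix requires >= 4 subjects")
    cols = list(score_table.columns)
    out: Dict[str, Dict[str, CorrelationCell]] = {c: {} for c in cols}
    for a in cols:
        for b in cols:
            try:
                out[a][b] = spearman_cell(score_table[a], score_table[b])
            except DegenerateInputError:
                out[a][b] = None  # type: ignore[assignment]
    return out


def matrix_to_frame(matrix: Dict[str, Dict[str, CorrelationCell]]) -> pd.DataFrame:
    """Flatten a correlation matrix into a table of r_s values."""
    cols = list(matrix)
    data = {
        a: [matrix[a][b].r_s if matrix[a][b] is not None else np.nan for b in cols]
        for a in cols
    }
    return pd.DataFrame(data, index=cols)
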