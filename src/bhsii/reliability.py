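"""Test-retest reliability and internal consistency.

Test-retest stability of the instrument is assessed on a control group of
healthy dogs administered the questionnaire twice two weeks apart, with the
intraclass correlation coefficient (ICC); internal consistency of the
24-item owner section is assessed at baseline with Cronbach's alpha.  Both
statistics are computed from their defining formulas so that the ANOVA
decomposition behind the ICC is auditable (the mean squares are retained
in the result).

ICC form
--------
The default is ICC(2,1) in the Shrout-Fleiss taxonomy: two-way random
effects, absolute agreement, single measurement —

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

with MS_R the between-subject, MS_C the between-administration and MS_E
the residual mean square, n subjects and k administrations.  A
consistency-form ICC(3,1) = (MS_R - MS_E)/(MS_R + (k-1) MS_E) is available
behind ``form="consistency"``.  An ICC >= 0.7 is conventionally taken to
indicate acceptable test-retest stability, and alpha > 0.7 acceptable
internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError

RELIABILITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its ANOVA decomposition."""

    icc_value: float
    model_label: str
    n_subjects: int
    n_administrations: int
    ms_subjects: float
    ms_administrations: float
    ms_residual: float

    @property
    def acceptable(self) -> bool:
        return self.icc_value >= RELIABILITY_THRESHOLD


@dataclass(frozen=True)
class AlphaResult:
    """Cronbach's alpha with the variance components it is built from."""

    alpha: float
    k: int
    item_variances: Tuple[float, ...]
    total_variance: float

    @property
    def acceptable(self) -> bool:
        return self.alpha > RELIABILITY_THRESHOLD


def _anova_mean_squares(data: np.ndarray) -> Tuple[float, float, float]:
    """Two-way ANOVA mean squares for an n x k (subjects x raters) table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_res = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_res = ss_res / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_res


def icc_test_retest(
    test: Sequence[float],
    retest: Sequence[float],
    form: str = "agreement",
) -> IccResult:
    """ICC between two administrations of the instrument, paired by subject.

    Parameters
    ----------
    test, retest
        Scores from the first and second administration, same subject order.
    form
        ``"agreement"`` for ICC(2,1) (default) or ``"consistency"`` for
        ICC(3,1).

    Raises
    ------
    DegenerateInputError
        For fewer than 3 subjects or zero total score variance.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or test.ndim != 1:
        raise ValueError("test and retest must be 1-d vectors of equal length")
    n = test.size
    if n < 3:
        raise DegenerateInputError(f"ICC requires at least 3 subjects, got {n}")
    data = np.column_stack([test, retest])
    if np.ptp(data) == 0:
        raise DegenerateInputError("all scores identical: ICC undefined")
    k = 2
    ms_r, ms_c, ms_e = _anova_mean_squares(data)
    if form == "agreement":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
        label = "ICC(2,1) two-way random, absolute agreement, single measure"
    elif form == "consistency":
        denom = ms_r + (k - 1) * ms_e
        label = "ICC(3,1) two-way mixed, consistency, single measure"
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise DegenerateInputError("zero ICC denominator: no variance to partition")
    icc = (ms_r - ms_e) / denom
    return IccResult(
        icc_value=float(icc),
        model_label=label,
        n_subjects=n,
        n_administrations=k,
        ms_subjects=ms_r,
        ms_administrations=ms_c,
        ms_residual=ms_e,
    )


def cronbach_alpha(item_matrix) -> AlphaResult:
    """Cronbach's alpha for a subjects x items score matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)),
    with unbiased (ddof=1) variances.

    Raises
    ------
    DegenerateInputError
        For fewer than 2 items, fewer than 3 subjects, or a constant
        total score.
    """
    data = np.asarray(item_matrix, dtype=float)
    if data.ndim != 2:
        raise ValueError("item_matrix must be 2-d (subjects x items)")
    n, k = data.shape
    if k < 2:
        raise DegenerateInputError(f"alpha requires at least 2 items, got {k}")
    if n < 3:
        raise DegenerateInputError(f"alpha requires at least 3 subjects, got {n}")
    if np.isnan(data).any():
        raise DegenerateInputError("item matrix contains missing values")
    item_var = data.var(axis=0, ddof=1)
    total_var = float(data.sum(axis=1).var(ddof=1))
    if total_var == 0:
        raise DegenerateInputError("constant total score: alpha undefined")
    alpha = k / (k - 1) * (1.0 - float(item_var.sum()) / total_var)
    return AlphaResult(
        alpha=float(alpha),
        k=k,
        item_variances=tuple(float(v) for v in item_var),
        total_variance=total_var,
    )
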