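"""ROC/AUC, exact binomial CIs and Spearman banding against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bhsii import (
    DegenerateInputError,
    clopper_pearson_ci,
    correlation_band,
    roc_analysis,
    spearman_cell,
    spearman_matrix,
)


def trapezoid_auc_oracle(diseased, healthy):
    """Area under the empirical ROC curve by the trapezoidal rule."""
    thresholds = np.unique(np.concatenate([diseased, healthy, [np.inf]]))
    # classify "diseased" when score <= t; sweep t upward
    sens = [(diseased <= t).mean() for t in thresholds]
    fpr = [(healthy <= t).mean() for t in thresholds]
    sens = np.concatenate([[0.0], sens])
    fpr = np.concatenate([[0.0], fpr])
    return float(np.trapezoid(sens, fpr))


class TestRoc:
    def test_disjoint_groups(self):
        res = roc_analysis([50, 60], [90, 95])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.separating_interval == (50.0, 60.0)
        assert res.threshold == 60.0

    def test_overlapping_groups_pairwise_count(self):
        # 9 pairs: healthy>diseased 6 wins, 2 ties, 1 loss -> 7/9
        res = roc_analysis([1, 2, 3], [2, 3, 4])
        assert res.auc == pytest.approx(7 / 9)
        assert res.separating_interval is None

    def test_pure_tie(self):
        assert roc_analysis([5], [5]).auc == 0.5

    def test_reversed_orientation_warns(self):
        with pytest.warns(UserWarning, match="orientation"):
            res = roc_analysis([90, 95], [50, 60])
        assert res.auc == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_analysis([], [1, 2])

    def test_youden_threshold_on_overlap(self):
        res = roc_analysis([10, 20, 30], [25, 40, 50])
        # t=20: sens 2/3, spec 1; t=30: sens 1, spec 2/3 -> both J=2/3;
        # the first maximizer in threshold order is reported
        assert res.threshold == 20.0
        assert res.sensitivity == pytest.approx(2 / 3)
        assert res.specificity == pytest.approx(1.0)

    @pytest.mark.filterwarnings("ignore:AUC < 0.5")
    def test_matches_trapezoid_oracle_on_random_inputs(self, rng):
        for _ in range(200):
            nd, nh = rng.integers(1, 21, 2)
            diseased = rng.integers(0, 15, nd).astype(float)
            healthy = rng.integers(0, 15, nh).astype(float)
            ours = roc_analysis(diseased, healthy).auc
            assert ours == pytest.approx(trapezoid_auc_oracle(diseased, healthy))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        diseased = rng.normal(50, 15, 40)
        healthy = rng.normal(80, 10, 25)
        labels = np.r_[np.zeros(40), np.ones(25)]
        expected = roc_auc_score(labels, np.r_[diseased, healthy])
        assert roc_analysis(diseased, healthy).auc == pytest.approx(expected)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "successes, n, expected_lower",
        [(158, 158, 0.977), (20, 20, 0.832)],
    )
    def test_full_success_lower_bounds(self, successes, n, expected_lower):
        lower, upper = clopper_pearson_ci(successes, n)
        assert upper == 1.0
        assert lower == pytest.approx(expected_lower, abs=5e-4)

    def test_boundary_closed_form(self):
        lower, upper = clopper_pearson_ci(10, 10)
        assert lower == pytest.approx(0.025 ** (1 / 10))
        lower0, upper0 = clopper_pearson_ci(0, 10)
        assert lower0 == 0.0
        assert upper0 == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_interval_brackets_point_estimate(self):
        for x, n in [(3, 10), (50, 60), (1, 200)]:
            lower, upper = clopper_pearson_ci(x, n)
            assert lower <= x / n <= upper

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            lower, upper = clopper_pearson_ci(int(0.8 * n), n)
            widths.append(upper - lower)
        assert widths == sorted(widths, reverse=True)

    def test_coverage_at_least_nominal(self, rng):
        p, n = 0.3, 25
        draws = rng.binomial(n, p, 2000)
        covered = np.mean(
            [lo <= p <= hi for lo, hi in (clopper_pearson_ci(x, n) for x in draws)]
        )
        assert covered >= 0.95

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(11, 10)


def spearman_oracle(x, y):
    """Midrank-then-Pearson from first principles."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for idx in order[i : j + 1]:
                ranks[idx] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_self_correlation(self, rng):
        x = rng.normal(0, 1, 10)
        cell = spearman_cell(x, x)
        assert cell.r_s == pytest.approx(1.0)
        assert cell.band == "very strong"

    def test_band_cuts(self):
        assert correlation_band(0.3635) == "weak"
        assert correlation_band(0.1) == "very weak"
        assert correlation_band(-0.45) == "moderate"
        assert correlation_band(0.79) == "strong"
        assert correlation_band(0.8) == "very strong"

    def test_tied_toy_matches_oracle(self):
        x = [1, 2, 2, 3, 5]
        y = [2, 1, 4, 4, 5]
        cell = spearman_cell(x, y)
        assert cell.r_s == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_oracle_on_random_ties(self, rng):
        for _ in range(100):
            n = rng.integers(4, 15)
            x = rng.integers(0, 5, n)
            y = rng.integers(0, 5, n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman_cell(x, y).r_s == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_exact_permutation_p_small_n(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        cell = spearman_cell(x, y, exact=True)
        r_obs = spearman_oracle(x, y)
        # brute-force reference over all 120 permutations
        import itertools

        count = 0
        perms = list(itertools.permutations(y))
        for p in perms:
            if abs(spearman_oracle(x, p)) >= abs(r_obs) - 1e-12:
                count += 1
        assert cell.p_value == pytest.approx(count / len(perms))

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        a = spearman_cell(x, y)
        b = spearman_cell(np.exp(x), y**3)
        assert a.r_s == pytest.approx(b.r_s)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matrix_symmetric_with_undefined_cells(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "a": rng.normal(0, 1, 8),
                "b": rng.normal(0, 1, 8),
                "const": np.ones(8),
            }
        )
        matrix = spearman_matrix(df)
        assert matrix["a"]["b"].r_s == pytest.approx(matrix["b"]["a"].r_s)
        assert matrix["a"]["const"] is None
        assert matrix["const"]["const"] is None
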