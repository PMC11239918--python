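"""Exact tests, odds ratios, logistic fits, rank AUC and t tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from celtilkit.stats import (
    StatsError,
    fisher_exact_2x2,
    fisher_exact_rxc,
    logistic_fit,
    odds_ratio,
    roc_auc,
    t_test,
)


def enumeration_fisher_2x2(table):
    """Independent oracle: explicit hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


def enumeration_freeman_halton(table):
    """Independent oracle for small r x c: brute-force over all tables."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())

    def prob(cells):
        logp = (
            sum(math.lgamma(r + 1) for r in rows)
            + sum(math.lgamma(c + 1) for c in cols)
            - math.lgamma(n + 1)
            - sum(math.lgamma(x + 1) for x in cells)
        )
        return math.exp(logp)

    p_obs = prob(t.ravel())
    total = 0.0
    # enumerate all non-negative integer tables with these margins
    r, c = t.shape
    def fill(row_idx, col_left, acc):
        nonlocal total
        if row_idx == r - 1:
            cells = acc + list(col_left)
            if all(x >= 0 for x in col_left) and sum(col_left) == rows[r - 1]:
                p = prob(cells)
                if p <= p_obs * (1 + 1e-7):
                    total += p
            return
        for combo in itertools.product(*(range(min(rows[row_idx], cl) + 1)
                                         for cl in col_left[:-1])):
            last = rows[row_idx] - sum(combo)
            if 0 <= last <= col_left[-1]:
                cells = list(combo) + [last]
                fill(row_idx + 1,
                     [cl - x for cl, x in zip(col_left, cells)],
                     acc + cells)
    fill(0, list(cols), [])
    return total


class TestFisher2x2:
    def test_printed_tp53_table(self):
        assert fisher_exact_2x2([[6, 3], [10, 30]]) == pytest.approx(0.043, abs=5e-4)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2([[0, 0], [10, 30]]) == pytest.approx(1.0)
        assert fisher_exact_2x2([[5, 0], [10, 0]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                enumeration_fisher_2x2(t.tolist()), abs=1e-9
            )


class TestFreemanHalton:
    def test_printed_her2_ihc_table(self):
        # HER2 0/1+/2+ rows x (responder, non-responder) columns
        table = [[10, 15], [13, 16], [3, 20]]
        assert fisher_exact_rxc(table) == pytest.approx(0.034, abs=5e-4)

    def test_reduces_to_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact_rxc(t) == pytest.approx(fisher_exact_2x2(t), abs=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc([[4, 6], [4, 6], [4, 6]]) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_3x2(self, rng):
        for _ in range(10):
            t = rng.integers(0, 7, size=(3, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_rxc(t) == pytest.approx(
                enumeration_freeman_halton(t), rel=1e-9, abs=1e-12
            )

    def test_too_large_refused_with_mc_hint(self):
        big = [[100, 100], [100, 100]]
        with pytest.raises(StatsError, match="Monte-Carlo"):
            fisher_exact_rxc(big, max_total=200)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[6, 3], [10, 30]], 6.00),
            ([[10, 1], [6, 32]], 53.33),
            ([[5, 5], [5, 5]], 1.0),
        ],
    )
    def test_cross_product_examples(self, table, expected):
        assert odds_ratio(table).effect == pytest.approx(expected, abs=5e-3)

    def test_ci_brackets_effect(self):
        r = odds_ratio([[6, 3], [10, 30]])
        assert r.ci_low <= r.effect <= r.ci_high

    def test_zero_cell_flagged(self):
        r = odds_ratio([[6, 0], [10, 30]])
        assert "zero_cell" in r.flags
        assert math.isinf(r.effect)
        corrected = odds_ratio([[6, 0], [10, 30]], haldane=True)
        assert "haldane_corrected" in corrected.flags
        assert math.isfinite(corrected.effect)


class TestLogistic:
    def test_univariate_binary_equals_cross_product_or(self):
        # expand the TP53 2x2 into per-sample records
        y = [1] * 6 + [0] * 3 + [1] * 10 + [0] * 30
        x = [1] * 9 + [0] * 40
        result = logistic_fit(y, x)[0]
        assert result.effect == pytest.approx(6.00, rel=1e-6)

    def test_independence_recovers_null_or(self, rng):
        x = rng.normal(size=10_000)
        y = rng.integers(0, 2, size=10_000)
        result = logistic_fit(y, x)[0]
        assert result.effect == pytest.approx(1.0, abs=0.1)
        assert result.ci_low < 1.0 < result.ci_high

    def test_perfect_separation_flagged(self):
        x = [0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        result = logistic_fit(y, x)[0]
        assert "separation" in result.flags or "non_converged" in result.flags

    def test_constant_covariate_rejected(self):
        with pytest.raises(StatsError):
            logistic_fit([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])

    def test_all_one_class_rejected(self):
        with pytest.raises(StatsError):
            logistic_fit([1, 1, 1], [1.0, 2.0, 3.0])

    def test_bivariate_adjustment_runs(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 * x1 + 0.8 * x2)))
        y = (rng.random(n) < p).astype(int)
        res = logistic_fit(y, np.column_stack([x1, x2]), names=["a", "b"])
        assert len(res) == 2
        assert res[0].method == "logistic:a"


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.effect == pytest.approx(1.0)

    def test_binary_predictor_closed_form(self):
        # positives score (1,1,1,0): sens 3/4; negatives (0,1,0,0,0,0): spec 5/6
        scores = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        sens, spec = 3 / 4, 5 / 6
        assert roc_auc(scores, labels).effect == pytest.approx((sens + spec) / 2)

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert roc_auc(scores, labels).effect == pytest.approx(0.5, abs=0.05)

    def test_one_class_rejected(self):
        with pytest.raises(StatsError):
            roc_auc([1.0, 2.0], [1, 1])

    @given(
        shift=st.floats(0.1, 3),
        scale=st.floats(0.1, 5),
    )
    def test_monotone_transform_invariance(self, shift, scale):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        base = roc_auc(scores, labels).effect
        assert roc_auc(scale * scores + shift, labels).effect == pytest.approx(base)
        assert roc_auc(np.exp(scores), labels).effect == pytest.approx(base)


class TestTTest:
    def test_identical_groups_p_one(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_welch(self):
        x = [4.0, 5.0, 6.0, 7.0]
        y = [1.0, 2.0, 3.0]
        nx, ny = 4, 3
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        se = math.sqrt(vx / nx + vy / ny)
        t = (np.mean(x) - np.mean(y)) / se
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        expected_p = 2 * sps.t.sf(abs(t), df)
        assert t_test(x, y).p_value == pytest.approx(expected_p)

    def test_paired_constant_difference_p_shrinks_with_n(self, rng):
        ps = []
        for n in (4, 16, 64):
            x = rng.normal(size=n)
            ps.append(t_test(x + 1.0 + rng.normal(0, 0.2, n), x, paired=True).p_value)
        assert ps[0] > ps[-1]

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            t_test([1.0, 1.0], [2.0, 2.0])
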