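import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eotrh_texture import (
    StatsConfig,
    ValidationError,
    compare_groups,
    compare_slopes,
    letter_display,
    normality_check,
)


class TestNormalityCheck:
    def test_normal_groups_take_parametric_branch_most_seeds(self):
        """Four Gaussian groups (n=30) pass the 4-test Shapiro battery at a
        rate consistent with its type-I error: all-pass probability is
        0.95^4 ~ 0.815, so over 50 seeds expect >= 0.815 - 2*SE ~ 70%."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(size=30) for g in range(4)}
            _, branch = normality_check(groups)
            hits += branch == "anova_tukey"
        assert hits >= 36

    def test_skewed_group_forces_nonparametric_branch(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(size=30) for g in range(3)}
        groups[3] = rng.exponential(scale=1.0, size=30) ** 3  # heavy skew
        _, branch = normality_check(groups)
        assert branch == "kw_dunn"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            normality_check({0: np.array([1.0, 2.0]), 1: np.random.normal(size=10)})


class TestCompareGroups:
    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        groups = {0: rng.normal(0, 1, 30), 1: rng.normal(5, 1, 30)}
        comp = compare_groups(groups)
        assert comp.letters[0] != comp.letters[1]
        assert len(set(comp.letters.values())) == 2

    def test_identical_distributions_share_letter_most_seeds(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(size=30) for g in range(4)}
            comp = compare_groups(groups)
            hits += len({v for v in comp.letters.values()}) == 1
        assert hits >= 45

    def test_staircase_pattern_letters_and_monotone_flag(self):
        # means 0, 5, 5, 10: lowest < (middle pair equal) < highest
        rng = np.random.default_rng(7)
        groups = {
            0: rng.normal(0, 1, 30),
            1: rng.normal(5, 1, 30),
            2: rng.normal(5, 1, 30),
            3: rng.normal(10, 1, 30),
        }
        comp = compare_groups(groups)
        assert comp.letters[0] == "a"
        assert comp.letters[1] == comp.letters[2] == "b"
        assert comp.letters[3] == "c"
        assert comp.monotone_increase_flag

    def test_constant_everywhere_is_degenerate(self):
        groups = {g: np.full(5, 3.14) for g in range(3)}
        comp = compare_groups(groups)
        assert comp.branch == "degenerate"
        assert comp.omnibus_p is None
        assert not comp.monotone_increase_flag

    def test_null_monotone_flag_rate_within_alpha(self):
        """Under identical group distributions the monotone-increase flag
        fires at most alpha + 2*SE of the time."""
        n_sim, hits = 400, 0
        for seed in range(n_sim):
            rng = np.random.default_rng(10_000 + seed)
            groups = {g: rng.normal(size=12) for g in range(4)}
            hits += compare_groups(groups).monotone_increase_flag
        alpha = 0.05
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert hits / n_sim <= alpha + 2 * se


class TestLetterDisplay:
    def test_all_significant_pairs_distinct_letters(self):
        labels = [0, 1, 2]
        p = {(0, 1): 0.001, (0, 2): 0.001, (1, 2): 0.001}
        letters = letter_display(labels, p, 0.05)
        assert len({letters[g] for g in labels}) == 3

    @settings(max_examples=200, deadline=None)
    @given(
        pvals=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=6, max_size=6),
    )
    def test_sharing_iff_not_significant(self, pvals):
        """Reconstructibility: two groups share a letter iff their pairwise
        p >= alpha, for arbitrary p maps over four groups."""
        labels = [0, 1, 2, 3]
        pairs = list(itertools.combinations(labels, 2))
        pmap = dict(zip(pairs, pvals))
        letters = letter_display(labels, pmap, 0.05)
        for (i, j), p in pmap.items():
            share = bool(set(letters[i]) & set(letters[j]))
            assert share == (p >= 0.05), (i, j, p, letters)


class TestCompareSlopes:
    def _series(self, slope, intercept, noise=0.0, seed=0, n_per_grade=5):
        rng = np.random.default_rng(seed)
        out = []
        for g in range(4):
            for _ in range(n_per_grade):
                out.append((g, slope * g + intercept + rng.normal(0, noise)))
        return out

    def test_identical_series_pool_to_common_slope(self):
        s = self._series(2.0, 1.0, noise=0.5, seed=3)
        comp = compare_slopes(s, list(s))
        assert comp.slope_equality_p == pytest.approx(1.0)
        assert comp.common_slope == pytest.approx(comp.slope_a)

    def test_parallel_noiseless_lines_share_slope_not_intercept(self):
        a = self._series(2.0, 0.0)
        b = self._series(2.0, 1.0)
        comp = compare_slopes(a, b)
        assert comp.slope_equality_p > 0.05
        assert comp.common_slope == pytest.approx(2.0, abs=1e-10)
        assert comp.intercept_equality_p < 0.05
        assert comp.common_intercept is None

    def test_different_noiseless_slopes_rejected(self):
        a = self._series(1.0, 0.0)
        b = self._series(3.0, 0.0)
        comp = compare_slopes(a, b)
        assert comp.slope_equality_p <= 0.05
        assert comp.common_slope is None

    def test_ols_recovers_generating_slope_exactly(self):
        a = self._series(0.731, -2.5)
        comp = compare_slopes(a, self._series(5.0, 0.0))
        assert comp.slope_a == pytest.approx(0.731, abs=1e-10)
        assert comp.intercept_a == pytest.approx(-2.5, abs=1e-10)

    def test_single_grade_series_rejected(self):
        with pytest.raises(ValidationError):
            compare_slopes([(1, 2.0), (1, 3.0)], [(0, 1.0), (1, 2.0)])
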