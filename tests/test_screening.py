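"""ANOVA screening and Duncan's multiple range test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kelptrace import (AnovaDuncanSelector, duncan_letters, oneway_anova,
                       screen_features)
from oracles import (anova_sums_of_squares, permutation_anova_pvalue,
                     two_group_duncan_range)


class TestOnewayAnova:
    def test_textbook_sums_of_squares(self):
        groups = [np.array([1., 2., 3.]), np.array([2., 3., 4.]),
                  np.array([3., 4., 5.])]
        f, p, mse, dfw = oneway_anova(*groups)
        ssb, ssw, f_o, p_o = anova_sums_of_squares(groups)
        # SS_between = 3*((2-3)^2 + 0 + (4-3)^2) = 6; each group contributes
        # (1+0+1) to SS_within, so SS_within = 6, MSE = 1, F = (6/2)/1 = 3
        assert (ssb, ssw) == (6.0, 6.0)
        assert f == pytest.approx(3.0) == pytest.approx(f_o)
        assert p == pytest.approx(p_o)
        assert dfw == 6 and mse == pytest.approx(1.0)

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(3)]
            f, p, _, _ = oneway_anova(*groups)
            sp = stats.f_oneway(*groups)
            assert f == pytest.approx(sp.statistic)
            assert p == pytest.approx(sp.pvalue)

    def test_all_identical_values(self):
        f, p, mse, _ = oneway_anova([5., 5., 5.], [5., 5., 5.], [5., 5., 5.])
        assert (f, p, mse) == (0.0, 1.0, 0.0)

    def test_zero_within_variance_separated_groups(self):
        f, p, _, _ = oneway_anova([1., 1.], [2., 2.])
        assert p == 0.0 and f == np.inf

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0], [2., 3.])
        with pytest.raises(ValueError):
            oneway_anova([1., np.inf], [2., 3.])
        with pytest.raises(ValueError):
            oneway_anova([1., 2.])

    def test_matches_permutation_pvalue(self, rng):
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.5, 0.2)]
        _, p, _, _ = oneway_anova(*groups)
        p_perm = permutation_anova_pvalue(groups, n_shuffles=10_000, seed=1)
        se = np.sqrt(p_perm * (1 - p_perm) / 10_000)
        assert abs(p - p_perm) < 4 * se + 1e-4


class TestDuncan:
    def test_equal_means_share_letter(self):
        letters = duncan_letters(np.array([3., 3., 3.]), np.array([5, 5, 5]),
                                 mse=1.0, df_within=12)
        assert letters == ["a", "a", "a"]

    def test_two_groups_match_t_based_oracle(self, rng):
        for _ in range(50):
            means = rng.normal(size=2) * 2
            mse = float(rng.uniform(0.1, 4.0))
            n = 10
            r2 = two_group_duncan_range(mse, 2 * (n - 1), n, alpha=0.05)
            letters = duncan_letters(means, np.array([n, n]), mse,
                                     2 * (n - 1))
            separated = abs(means[0] - means[1]) > r2
            assert (letters[0] != letters[1]) == separated

    def test_relabeling_invariance(self, rng):
        means = rng.normal(size=3)
        sizes = np.array([8, 8, 8])
        base = duncan_letters(means, sizes, 1.3, 21)
        perm = np.array([2, 0, 1])
        relabeled = duncan_letters(means[perm], sizes[perm], 1.3, 21)
        assert [relabeled[list(perm).index(i)] for i in range(3)] == base

    def test_location_shift_invariance(self, rng):
        means = rng.normal(size=3)
        sizes = np.array([6, 6, 6])
        assert duncan_letters(means, sizes, 0.8, 15) == \
            duncan_letters(means + 100.0, sizes, 0.8, 15)

    def test_letters_reflect_rank_order(self):
        # widely separated means get distinct letters a > b > c by mean rank
        letters = duncan_letters(np.array([0., 10., 5.]),
                                 np.array([10, 10, 10]), 1.0, 27)
        assert letters == ["c", "a", "b"]

    def test_df_error(self):
        with pytest.raises(ValueError):
            duncan_letters(np.array([1., 2.]), np.array([3, 3]), 1.0, 0)


class TestScreening:
    def test_seed1_acetic_acid(self, seed1_run):
        r = next(x for x in seed1_run["report"].results
                 if x.feature_id == "A21")
        assert r.p_value < 0.001
        # Xiapu largest (a), Rongcheng middle (b), Dalian smallest (c)
        assert r.duncan_letters == ("b", "c", "a")
        assert r.df_within == 87

    def test_seed1_selection_near_107(self, seed1_run):
        assert abs(len(seed1_run["report"].selected_ids) - 107) <= 3

    def test_selected_order_and_reduction(self, seed1_cohort, seed1_run):
        report, reduced = seed1_run["report"], seed1_run["reduced"]
        assert reduced.feature_ids == report.selected_ids
        order = {f: i for i, f in enumerate(seed1_cohort.feature_ids)}
        idx = [order[f] for f in report.selected_ids]
        assert idx == sorted(idx)

    def test_alpha_zero_selects_nothing(self, seed1_cohort):
        report, reduced = screen_features(seed1_cohort, alpha=0.0)
        assert report.selected_ids == [] and reduced.n_features == 0

    def test_selector_sklearn_contract(self, rng):
        X = rng.normal(size=(30, 6))
        X[:, 0] += np.repeat([0, 3, 6], 10)  # one strong feature
        y = np.repeat([0, 1, 2], 10)
        sel = AnovaDuncanSelector(alpha=0.01).fit(X, y)
        assert sel.get_support()[0]
        assert sel.transform(X).shape == (30, int(sel.get_support().sum()))
        assert sel.get_params()["alpha"] == 0.01

    def test_type_one_error_calibrated(self, rng):
        # null features: identical group distributions
        n_feat = 1000
        X = rng.normal(size=(90, n_feat))
        y = np.repeat([0, 1, 2], 30)
        rejections = sum(
            oneway_anova(X[y == 0, j], X[y == 1, j], X[y == 2, j])[1] < 0.05
            for j in range(n_feat)
        )
        assert 0.03 <= rejections / n_feat <= 0.07


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_anova_nonnegative_f_and_valid_p(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.normal(size=rng.integers(2, 9)) for _ in range(3)]
    f, p, mse, dfw = oneway_anova(*groups)
    assert f >= 0 and 0 <= p <= 1 and mse >= 0
    assert dfw == sum(len(g) for g in groups) - 3
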