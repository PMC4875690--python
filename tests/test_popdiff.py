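"""V_ST, the CN t-test and the top-5% + p<0.05 selection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cnvpop.popdiff import (
    InsufficientDataError,
    cn_ttest,
    select_differentiated,
    vst,
)
from cnvpop.simulate import simulate_cn_matrix


def brute_force_vst(a, b):
    """Direct evaluation of (V_T - V_S)/V_T with population variances."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    v_t = ((pooled - pooled.mean()) ** 2).sum() / pooled.size
    var_a = ((a - a.mean()) ** 2).sum() / a.size
    var_b = ((b - b.mean()) ** 2).sum() / b.size
    v_s = (a.size * var_a + b.size * var_b) / (a.size + b.size)
    return (v_t - v_s) / v_t if v_t > 0 else None


class TestVst:
    def test_identical_distributions_give_zero(self):
        r = vst([2, 4], [2, 4])
        assert (r.v_t, r.v_s, r.v_st) == (1.0, 1.0, 0.0)
        assert r.defined

    def test_fixed_between_group_difference_gives_one(self):
        r = vst([2, 2], [4, 4])
        assert (r.v_t, r.v_s, r.v_st) == (1.0, 0.0, 1.0)

    def test_weighted_formula_matches_brute_force(self):
        a, b = [2, 2, 3], [4, 5, 4, 5]
        assert vst(a, b).v_st == pytest.approx(brute_force_vst(a, b), abs=1e-12)

    def test_zero_total_variance_flagged_undefined(self):
        r = vst([2, 2], [2, 2])
        assert not r.defined and r.v_st == 0.0

    def test_undersized_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            vst([2], [2, 3])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        a=st.lists(st.integers(0, 6), min_size=2, max_size=20),
        b=st.lists(st.integers(0, 6), min_size=2, max_size=20),
    )
    def test_matches_oracle_and_is_label_and_shift_invariant(self, a, b):
        r = vst(a, b)
        expected = brute_force_vst(a, b)
        if expected is None:
            assert not r.defined
            return
        assert r.v_st == pytest.approx(expected, abs=1e-12)
        assert r.v_st <= 1.0
        # relabeling the groups changes nothing
        assert vst(b, a).v_st == pytest.approx(r.v_st, abs=1e-12)
        # adding a constant changes nothing; scaling keeps the variance ratio
        shifted = vst([x + 3 for x in a], [x + 3 for x in b])
        assert shifted.v_st == pytest.approx(r.v_st, abs=1e-9)
        scaled = vst([x * 2.5 for x in a], [x * 2.5 for x in b])
        assert scaled.v_st == pytest.approx(r.v_st, abs=1e-9)


class TestCnTtest:
    def test_identical_vectors_give_p_one(self):
        assert cn_ttest([2, 2, 3], [2, 2, 3]) == pytest.approx(1.0)

    def test_zero_variance_unequal_means_give_p_zero(self):
        assert cn_ttest([2, 2, 2], [4, 4, 4]) == 0.0

    def test_zero_variance_equal_means_give_p_one(self):
        assert cn_ttest([3, 3], [3, 3]) == 1.0

    def test_matches_textbook_pooled_t(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        # closed form: pooled sd, t, and the t CDF
        sp2 = (3 * np.var(a, ddof=1) + 3 * np.var(b, ddof=1)) / 6
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        expected = 2 * sps.t.sf(abs(t), df=6)
        assert cn_ttest(a, b) == pytest.approx(expected, abs=1e-12)

    def test_type_i_error_calibrated_under_permutation_null(self):
        rng = np.random.default_rng(99)
        hits = 0
        n = 500
        for _ in range(n):
            pooled = rng.normal(2.0, 0.5, 20)
            rng.shuffle(pooled)
            hits += cn_ttest(pooled[:10], pooled[10:]) < 0.05
        assert 0.03 <= hits / n <= 0.07


class TestSelectDifferentiated:
    def test_single_fixed_split_among_permuted_neutrals(self):
        rng = np.random.default_rng(1)
        samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=samples)
        rows = {"planted": [2.0] * 10 + [4.0] * 10}
        half = np.array([2.0] * 5 + [4.0] * 5)
        for i in range(99):
            # identical CN distributions in both groups, order shuffled
            rows[f"neutral{i}"] = np.concatenate(
                [rng.permutation(half), rng.permutation(half)]
            )
        matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        results = select_differentiated(matrix, groups)
        selected = {r.cnvr_id for r in results if r.selected}
        assert selected == {"planted"}

    def test_all_constant_rows_select_nothing(self):
        samples = [f"s{i}" for i in range(8)]
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        matrix = pd.DataFrame(2.0, index=["r1", "r2"], columns=samples)
        results = select_differentiated(matrix, groups)
        assert not any(r.selected for r in results)
        assert not any(r.defined for r in results)

    def test_recovery_of_planted_differentiated_rows(self):
        matrix, groups, diff_ids = simulate_cn_matrix(
            n_neutral=200, n_differentiated=10, n_per_group=(20, 20),
            diff_cn=4, diff_freq=(0.95, 0.05), seed=21,
        )
        results = select_differentiated(matrix, groups)
        selected = {r.cnvr_id for r in results if r.selected}
        assert len(selected & set(diff_ids)) >= 9
        neutral_selected = selected - set(diff_ids)
        assert len(neutral_selected) <= 0.05 * 200

    def test_more_than_two_groups_rejected(self):
        samples = ["a", "b", "c", "d"]
        matrix = pd.DataFrame(2.0, index=["r"], columns=samples)
        groups = pd.Series(["A", "B", "C", "A"], index=samples)
        with pytest.raises(ValueError):
            select_differentiated(matrix, groups)

    def test_undersized_group_rejected(self):
        samples = ["a", "b", "c"]
        matrix = pd.DataFrame(2.0, index=["r"], columns=samples)
        groups = pd.Series(["A", "B", "B"], index=samples)
        with pytest.raises(InsufficientDataError):
            select_differentiated(matrix, groups)
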