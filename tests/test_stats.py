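"""Statistics: Fisher's ratio, AUROC, KS normality, nested permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edapain.records import ValidationError
from edapain.stats import auroc, fishers_ratio, ks_normality, nested_rank_test


def auroc_brute_force(scores, labels):
    """Pair counting: P(score_1 > score_0) with ties counting one half."""
    s1 = scores[labels == 1]
    s0 = scores[labels == 0]
    wins = 0.0
    for a in s1:
        for b in s0:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(s1) * len(s0))


class TestFishersRatio:
    def test_hand_computed_example(self):
        assert fishers_ratio([0, 2], [4, 6]) == pytest.approx(1.0)

    def test_identical_classes_give_zero(self):
        assert fishers_ratio([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(0)
        x0, x1 = rng.standard_normal(20), rng.standard_normal(20) + 1.0
        base = fishers_ratio(x0, x1)
        assert fishers_ratio(x0 + 5.0, x1 + 5.0) == pytest.approx(base, rel=1e-12)
        assert fishers_ratio(3.0 * x0, 3.0 * x1) == pytest.approx(base / 3.0, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fishers_ratio([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValidationError):
            fishers_ratio([1.0], [2.0, 3.0])


class TestAuroc:
    def test_pair_counting_example(self):
        auc, _, _ = auroc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        auc, _, _ = auroc(np.array([1, 2, 3, 11, 12, 13.0]), np.array([0, 0, 0, 1, 1, 1]))
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = auroc(np.ones(8), np.array([0, 1] * 4))
        assert auc == 0.5

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 50))
    def test_matches_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 10, n).astype(float)  # many ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        auc, _, _ = auroc(scores, labels, n_boot=10)
        assert auc == pytest.approx(auroc_brute_force(scores, labels), abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1.5, 1, 50)])
        labels = np.repeat([0, 1], 50)
        subjects = np.tile(np.repeat(np.arange(10), 5), 2)
        auc, lo, hi = auroc(scores, labels, subjects, seed=1)
        assert lo <= auc <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc(np.arange(4.0), np.ones(4, int))


class TestKsNormality:
    def test_calibration_on_normal_and_exponential(self):
        keep_normal = 0
        reject_expon = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            if ks_normality(rng.standard_normal(500)) > 0.05:
                keep_normal += 1
            if ks_normality(rng.exponential(size=500)) < 0.05:
                reject_expon += 1
        assert keep_normal >= 90
        assert reject_expon >= 90

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality(np.arange(4.0))


class TestNestedRankTest:
    @staticmethod
    def _dataset(rng, n_subjects=5, n_per=20, shift=0.0):
        values, labels, subjects = [], [], []
        for s in range(n_subjects):
            base = rng.normal(0, 1, n_per) + rng.normal(0, 2)  # subject level offset
            lab = np.repeat([0, 1], n_per // 2)
            base[lab == 1] += shift
            values.append(base)
            labels.append(lab)
            subjects.append(np.full(n_per, s))
        return np.concatenate(values), np.concatenate(labels), np.concatenate(subjects)

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_datasets = 200
        for rep in range(n_datasets):
            rng = np.random.default_rng(rep)
            v, l, s = self._dataset(rng, shift=0.0)
            p = nested_rank_test(v, l, s, n_perm=400, seed=rep)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_datasets <= 0.09

    def test_complete_separation_gives_minimal_p(self):
        rng = np.random.default_rng(9)
        v, l, s = self._dataset(rng, shift=50.0)
        p = nested_rank_test(v, l, s, n_perm=999, seed=0)
        assert p < 0.01

    def test_single_subject_reduces_to_rank_sum_permutation(self):
        rng = np.random.default_rng(11)
        v = rng.normal(0, 1, 24)
        l = np.repeat([0, 1], 12)
        v[l == 1] += 1.2
        s = np.zeros(24)
        p_nested = nested_rank_test(v, l, s, n_perm=5000, seed=3)
        # direct within-subject permutation of the rank-sum statistic
        from scipy.stats import rankdata

        ranks = rankdata(v)
        obs = ranks[l == 1].sum()
        rng2 = np.random.default_rng(123)
        null = np.array([ranks[rng2.permutation(l) == 1].sum() for _ in range(5000)])
        p_direct = (1 + np.sum(np.abs(null - null.mean()) >= abs(obs - null.mean()))) / 5001
        assert p_nested == pytest.approx(p_direct, abs=0.02)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(21)
        v, l, s = self._dataset(rng, shift=0.4)
        p1 = nested_rank_test(v, l, s, n_perm=500, seed=7)
        p2 = nested_rank_test(v, l, s, n_perm=500, seed=7)
        assert p1 == p2

    def test_subject_without_both_classes_excluded(self):
        v = np.concatenate([np.arange(10.0), np.arange(5.0)])
        l = np.concatenate([np.repeat([0, 1], 5), np.ones(5, int)])
        s = np.concatenate([np.zeros(10), np.ones(5)])
        p = nested_rank_test(v, l, s, n_perm=200, seed=0)
        assert 0.0 < p <= 1.0
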