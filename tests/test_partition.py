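"""Grouped 64/16/20 splitting: clustering, rounding, disjointness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ganfe
from ganfe.cohort import Cohort, FeatureMeta
from ganfe.partition import _largest_remainder


def _cohort(X, y=None):
    X = np.asarray(X, dtype=float)
    meta = [FeatureMeta(f"f{j}", "clinical-continuous")
            for j in range(X.shape[1])]
    y = np.zeros(X.shape[0], dtype=int) if y is None else np.asarray(y)
    ids = np.array([f"r{i}" for i in range(X.shape[0])])
    return Cohort(ids, X, y, meta)


class TestClusterGroups:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(100, 2))
        b = rng.normal(8, 0.3, size=(100, 2))
        cohort = _cohort(np.vstack([a, b]))
        labels = ganfe.cluster_groups(cohort, k=2, seed=0)
        first, second = labels[:100], labels[100:]
        agree = max(np.mean(first == 0) + np.mean(second == 1),
                    np.mean(first == 1) + np.mean(second == 0)) / 2
        assert agree >= 0.99

    def test_k_one_single_group(self, small_cohort):
        assert set(ganfe.cluster_groups(small_cohort, k=1)) == {0}

    def test_deterministic_given_seed(self, small_cohort):
        a = ganfe.cluster_groups(small_cohort, k=3, seed=7)
        b = ganfe.cluster_groups(small_cohort, k=3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ganfe.cluster_groups(_cohort(np.ones((3, 2))), k=5)


class TestLargestRemainder:
    @pytest.mark.parametrize("n,fractions,expected", [
        (100, (0.64, 0.16, 0.20), [64, 16, 20]),
        (5, (0.64, 0.16, 0.20), [3, 1, 1]),   # remainders 0.2, 0.8, 0.0
        (7, (0.64, 0.16, 0.20), [5, 1, 1]),   # remainders .48, .12, .40
        (3, (1.0, 0.0, 0.0), [3, 0, 0]),
    ])
    def test_hand_enumerated_allocations(self, n, fractions, expected):
        assert _largest_remainder(n, fractions) == expected

    @given(st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_allocation_sums_to_n(self, n):
        counts = _largest_remainder(n, (0.64, 0.16, 0.20))
        assert sum(counts) == n
        assert all(c >= 0 for c in counts)


class TestStratifiedSplit:
    def test_single_group_of_100(self):
        cohort = _cohort(np.random.default_rng(1).normal(size=(100, 3)))
        split = ganfe.stratified_split(cohort, np.zeros(100, dtype=int),
                                       seed=0)
        assert (len(split.train), len(split.test),
                len(split.validation)) == (64, 16, 20)

    def test_degenerate_fractions_all_train(self):
        cohort = _cohort(np.ones((9, 2)))
        split = ganfe.stratified_split(cohort, np.zeros(9, dtype=int),
                                       fractions=(1.0, 0.0, 0.0), seed=0)
        assert len(split.train) == 9 and len(split.test) == 0

    def test_bad_fractions_rejected(self):
        cohort = _cohort(np.ones((4, 1)))
        with pytest.raises(ValueError, match="sum to 1"):
            ganfe.stratified_split(cohort, np.zeros(4, dtype=int),
                                   fractions=(0.5, 0.2, 0.2))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_disjoint_and_exhaustive_for_every_seed(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 60))
        cohort = _cohort(rng.normal(size=(n, 3)))
        groups = rng.integers(0, 3, size=n)
        split = ganfe.stratified_split(cohort, groups, seed=seed)
        ids = (set(split.train.tolist()) | set(split.test.tolist())
               | set(split.validation.tolist()))
        assert ids == set(cohort.ids.tolist())
        assert (len(split.train) + len(split.test)
                + len(split.validation)) == n

    def test_per_group_fractions_within_one_record(self):
        rng = np.random.default_rng(4)
        n = 240
        cohort = _cohort(rng.normal(size=(n, 2)))
        groups = rng.integers(0, 3, size=n)
        split = ganfe.stratified_split(cohort, groups, seed=1)
        masks = split.masks(cohort.ids)
        for g in range(3):
            in_g = groups == g
            ng = int(in_g.sum())
            for part, frac in (("train", 0.64), ("test", 0.16),
                               ("validation", 0.20)):
                got = int((masks[part] & in_g).sum())
                assert abs(got - frac * ng) <= 1

    def test_class_ratio_tracks_overall(self):
        rng = np.random.default_rng(5)
        n = 1000
        y = (rng.random(n) < 0.3).astype(int)
        cohort = _cohort(rng.normal(size=(n, 2)), y=y)
        groups = rng.integers(0, 3, size=n)
        split = ganfe.stratified_split(cohort, groups, seed=2)
        masks = split.masks(cohort.ids)
        overall = y.mean()
        for part in ("train", "test", "validation"):
            part_rate = y[masks[part]].mean()
            assert abs(part_rate - overall) < 0.08

    def test_split_json_round_trip(self, tmp_path, small_cohort):
        groups = ganfe.cluster_groups(small_cohort, k=3, seed=0)
        split = ganfe.stratified_split(small_cohort, groups, seed=0)
        path = tmp_path / "split.json"
        split.to_json(path)
        back = ganfe.SplitIndices.from_json(path)
        np.testing.assert_array_equal(np.sort(back.train),
                                      np.sort(split.train))
        np.testing.assert_array_equal(back.group_labels, split.group_labels)
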