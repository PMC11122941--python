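"""SMOTE, ENN and the iterative balancing schedule, checked against
independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ganfe.resample import (GAN_GENERATED, OBSERVED, SMOTE_SYNTHETIC, enn,
                            iterative_balance, smote)


def _on_segment(point, a, b, tol=1e-9):
    """Brute-force oracle: is `point` on the segment [a, b]?"""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.allclose(point, a, atol=tol)
    t = float((point - a) @ ab) / denom
    return -tol <= t <= 1 + tol and np.allclose(a + t * ab, point, atol=1e-8)


def _enn_oracle(records, labels, k):
    """Independent ENN: per-record neighbour vote by explicit loops."""
    keep = []
    for i in range(len(records)):
        d = np.linalg.norm(records - records[i], axis=1)
        d[i] = np.inf
        nn = np.argsort(d)[:k]
        votes = labels[nn]
        other = np.sum(votes != labels[i])
        if other <= k / 2:  # no strict majority against the record
            keep.append(i)
    return np.array(keep)


class TestSmote:
    def test_two_point_minority_all_on_segment(self):
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        out = smote(minority, n_new=40, k=1, seed=0)
        for pt in out:
            assert _on_segment(pt, minority[0], minority[1])

    def test_zero_requested_empty(self):
        assert smote(np.eye(3), n_new=0).shape == (0, 3)

    def test_every_synthetic_point_on_a_minority_segment(self):
        rng = np.random.default_rng(1)
        minority = rng.random((12, 3))
        out = smote(minority, n_new=60, k=5, seed=2)
        dist = cdist(minority, minority)
        np.fill_diagonal(dist, np.inf)
        nn = np.argsort(dist, axis=1)[:, :5]
        for pt in out:
            assert any(_on_segment(pt, minority[i], minority[j])
                       for i in range(12) for j in nn[i])

    def test_convex_hull_membership_via_coordinates(self):
        rng = np.random.default_rng(3)
        minority = rng.random((20, 4))
        out = smote(minority, n_new=100, k=5, seed=4)
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_k_lowered_when_minority_small(self, caplog):
        minority = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with caplog.at_level("WARNING"):
            out = smote(minority, n_new=10, k=5, seed=0)
        assert out.shape == (10, 2)
        assert any("lowering k" in r.message for r in caplog.records)

    def test_deterministic_given_seed(self):
        minority = np.random.default_rng(5).random((8, 2))
        a = smote(minority, 20, seed=7)
        b = smote(minority, 20, seed=7)
        np.testing.assert_array_equal(a, b)


class TestEnn:
    def test_single_class_nothing_removed(self):
        rng = np.random.default_rng(0)
        X = rng.random((15, 2))
        keep = enn(X, np.ones(15, dtype=int), k=3)
        assert keep.tolist() == list(range(15))

    def test_lone_intruder_removed(self):
        cluster = np.random.default_rng(1).normal(0, 0.05, size=(10, 2))
        X = np.vstack([cluster, [[0.0, 0.0]]])
        y = np.array([0] * 10 + [1])
        keep = enn(X, y, k=3)
        assert 10 not in keep

    def test_two_far_clusters_untouched_and_idempotent(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(12, 2))
        b = rng.normal(10, 0.1, size=(12, 2))
        X = np.vstack([a, b])
        y = np.array([0] * 12 + [1] * 12)
        keep = enn(X, y, k=3)
        assert keep.tolist() == list(range(24))
        keep2 = enn(X[keep], y[keep], k=3)
        assert keep2.tolist() == list(range(24))

    def test_retained_set_is_subset_of_input(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 3))
        y = rng.integers(0, 2, size=30)
        keep = enn(X, y, k=3)
        assert set(keep.tolist()) <= set(range(30))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("k", [1, 3, 4])
    def test_matches_brute_force_oracle_on_small_instances(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        X = rng.random((n, 2))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        got = enn(X, y, k=k)
        want = _enn_oracle(X, y, k)
        np.testing.assert_array_equal(got, want)


class TestIterativeBalance:
    @staticmethod
    def _imbalanced(seed=0, n_maj=260, n_min=20):
        rng = np.random.default_rng(seed)
        # overlapping classes so ENN has borderline points to erode
        X = np.vstack([rng.normal(0.4, 0.2, size=(n_maj, 3)),
                       rng.normal(0.6, 0.2, size=(n_min, 3))])
        y = np.array([0] * n_maj + [1] * n_min)
        prov = np.full(len(y), OBSERVED)
        pending = rng.normal(0.6, 0.2, size=(500, 3))
        return X, y, prov, pending

    def test_terminates_with_majority_at_most_target(self):
        X, y, prov, pending = self._imbalanced()
        out = iterative_balance(X, y, prov, pending, batch=100,
                                target_majority=200, repeats=2, seed=0)
        assert out.majority_count <= 200
        assert len(out.iteration_log) >= 1

    def test_zero_pending_single_pass(self):
        X, y, prov, _ = self._imbalanced()
        out = iterative_balance(X, y, prov, np.empty((0, 3)), batch=100,
                                target_majority=200, repeats=1, seed=0)
        assert len(out.iteration_log) == 1
        assert set(out.provenance) <= {OBSERVED, SMOTE_SYNTHETIC}

    def test_target_above_initial_majority_single_iteration(self):
        X, y, prov, pending = self._imbalanced()
        out = iterative_balance(X, y, prov, pending, batch=100,
                                target_majority=10_000, repeats=1, seed=0)
        assert len(out.iteration_log) == 1
        assert out.iteration_log[0]["added_generated"] == 100

    def test_provenance_tracked_through_deletions(self):
        X, y, prov, pending = self._imbalanced()
        out = iterative_balance(X, y, prov, pending, batch=100,
                                target_majority=200, repeats=2, seed=0)
        kinds = set(out.provenance.tolist())
        assert kinds <= {OBSERVED, GAN_GENERATED, SMOTE_SYNTHETIC}
        assert GAN_GENERATED in kinds
        # generated and synthetic records are all positive
        for kind in (GAN_GENERATED, SMOTE_SYNTHETIC):
            mask = out.provenance == kind
            if mask.any():
                assert (out.y[mask] == 1).all()

    def test_iteration_log_reproducible(self):
        X, y, prov, pending = self._imbalanced()
        a = iterative_balance(X, y, prov, pending, target_majority=200,
                              repeats=2, seed=3)
        b = iterative_balance(X, y, prov, pending, target_majority=200,
                              repeats=2, seed=3)
        assert a.iteration_log == b.iteration_log
        np.testing.assert_array_equal(a.X, b.X)
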