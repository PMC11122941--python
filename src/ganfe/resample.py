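"""From-scratch SMOTE, edited-nearest-neighbour (ENN) cleaning, and the
iterative batch-of-100 balancing schedule.

The schedule mixes pending GAN-generated positives into the combined
training set 100 at a time; after each addition, SMOTE equalizes the class
counts by interpolating new minority points between nearest minority
neighbours, then ENN deletes records whose k-nearest-neighbour majority
vote disagrees with their own label. Iteration stops at the first pass
where the majority-class count has come down to the target (default 1000)
or the pending pool is exhausted. Provenance (observed / gan-generated /
smote-synthetic) is tracked through every deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["BalancedSet", "smote", "enn", "iterative_balance",
           "OBSERVED", "GAN_GENERATED", "SMOTE_SYNTHETIC"]

log = logging.getLogger(__name__)

OBSERVED = "observed"
GAN_GENERATED = "gan-generated"
SMOTE_SYNTHETIC = "smote-synthetic"


@dataclass
class BalancedSet:
    """Balanced records with per-record provenance and an iteration log."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # str per record
    iteration_log: list[dict] = field(default_factory=list)

    @property
    def majority_count(self) -> int:
        return int(np.sum(self.y == 0))

    @property
    def minority_count(self) -> int:
        return int(np.sum(self.y == 1))


def smote(minority_records: np.ndarray, n_new: int, k: int = 5,
          seed: int = 0) -> np.ndarray:
    """Interpolated synthetic minority records.

    Each synthetic record is x + lambda * (x_nn - x) with x a uniformly
    sampled minority record, x_nn one of its k nearest minority neighbours
    (Euclidean, self excluded) and lambda ~ Uniform(0, 1); all outputs lie
    on segments between minority points, hence in their convex hull. If
    fewer than k+1 minority records exist, k is lowered to count-1 with a
    logged warning.
    """
    minority_records = np.asarray(minority_records, dtype=float)
    m = minority_records.shape[0]
    if n_new == 0:
        return np.empty((0, minority_records.shape[1]))
    if m < 2:
        raise ValueError("need at least 2 minority records for SMOTE")
    if m <= k:
        log.warning("SMOTE: k=%d >= minority count %d; lowering k to %d",
                    k, m, m - 1)
        k = m - 1
    dist = cdist(minority_records, minority_records)
    np.fill_diagonal(dist, np.inf)
    nn_idx = np.argsort(dist, axis=1)[:, :k]  # k nearest, self excluded

    rng = np.random.default_rng(seed)
    base = rng.integers(0, m, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.random(n_new)[:, None]
    x = minority_records[base]
    x_nn = minority_records[nn_idx[base, pick]]
    return x + lam * (x_nn - x)


def enn(records: np.ndarray, labels: np.ndarray, k: int = 3) -> np.ndarray:
    """Indices retained after edited-nearest-neighbour cleaning.

    A record is deleted when the majority vote of its k nearest neighbours
    (self excluded) disagrees with its own label. Votes are computed on the
    original set and deletions applied simultaneously, so the result does
    not depend on record order. Tie votes (possible with even k) count as
    agreement and retain the record.
    """
    records = np.asarray(records, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    n = records.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} records")
    if len(np.unique(labels)) < 2:
        return np.arange(n)
    dist = cdist(records, records)
    np.fill_diagonal(dist, np.inf)
    nn_idx = np.argsort(dist, axis=1)[:, :k]
    votes = labels[nn_idx].mean(axis=1)
    # disagreement: strict majority of neighbours has the other label
    remove = np.where(labels == 1, votes < 0.5, votes > 0.5)
    return np.flatnonzero(~remove)


def _one_smote_enn_pass(X, y, prov, k_smote, k_enn, seed):
    """Equalize classes with SMOTE, then clean with ENN."""
    n_min, n_maj = int(np.sum(y == 1)), int(np.sum(y == 0))
    n_new = max(n_maj - n_min, 0)
    if n_new > 0 and np.sum(y == 1) >= 2:
        synth = smote(X[y == 1], n_new, k=k_smote, seed=seed)
        X = np.vstack([X, synth])
        y = np.concatenate([y, np.ones(n_new, dtype=int)])
        prov = np.concatenate([prov, np.full(n_new, SMOTE_SYNTHETIC)])
    keep = enn(X, y, k=k_enn)
    return X[keep], y[keep], prov[keep]


def iterative_balance(X: np.ndarray, y: np.ndarray, provenance: np.ndarray,
                      pending_generated: np.ndarray, batch: int = 100,
                      target_majority: int = 1000, repeats: int = 2,
                      k_smote: int = 5, k_enn: int = 3,
                      seed: int = 0) -> BalancedSet:
    """Iterative SMOTE+ENN balancing with batch-wise generated additions.

    Starting from the observed training records (X, y, provenance), each
    iteration appends the next `batch` pending GAN-generated records
    (labelled positive), applies the SMOTE+ENN pass `repeats` times, and
    logs the class counts. The loop terminates at the first iteration where
    the majority-class count is <= `target_majority`, or when the pending
    pool is exhausted. `repeats=0` only mixes in the generated records.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    prov = np.asarray(provenance).astype(object)
    pending = np.asarray(pending_generated, dtype=float)
    if int(np.sum(y == 0)) <= target_majority:
        log.info("majority count %d already <= target %d; single pass",
                 int(np.sum(y == 0)), target_majority)

    logbook: list[dict] = []
    offset = 0
    iteration = 0
    while True:
        chunk = pending[offset:offset + batch]
        offset += chunk.shape[0]
        if chunk.shape[0]:
            X = np.vstack([X, chunk])
            y = np.concatenate([y, np.ones(chunk.shape[0], dtype=int)])
            prov = np.concatenate([prov,
                                   np.full(chunk.shape[0], GAN_GENERATED)])
        for r in range(repeats):
            X, y, prov = _one_smote_enn_pass(
                X, y, prov, k_smote, k_enn,
                seed=seed + 1000 * iteration + r)
        n_maj, n_min = int(np.sum(y == 0)), int(np.sum(y == 1))
        logbook.append({"iteration": iteration,
                        "added_generated": int(chunk.shape[0]),
                        "majority": n_maj, "minority": n_min,
                        "total": int(y.size)})
        iteration += 1
        if n_maj <= target_majority or offset >= pending.shape[0]:
            break
    return BalancedSet(X, y, prov, logbook)
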