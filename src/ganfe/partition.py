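"""Feature-stratified train/test/validation partitioning.

Records are first clustered into k groups (default 3) by k-means on the
normalized feature matrix, then each group is split 64/16/20 into
train/test/validation and the per-group splits are merged. Stratifying on
feature clusters (not on the outcome) keeps each partition representative of
the cohort's covariate structure; with severe class imbalance the class
ratio in each partition then tracks the overall ratio up to sampling error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .cohort import Cohort

__all__ = ["SplitIndices", "cluster_groups", "stratified_split"]


@dataclass
class SplitIndices:
    """Disjoint, exhaustive id sets for the three partitions."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    group_labels: np.ndarray  # per-record group, aligned with the cohort

    def __post_init__(self):
        parts = [set(self.train.tolist()), set(self.test.tolist()),
                 set(self.validation.tolist())]
        total = sum(len(s) for s in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("partitions overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train": self.train.tolist(),
            "test": self.test.tolist(),
            "validation": self.validation.tolist(),
            "group_labels": self.group_labels.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["train"]), np.array(d["test"]),
                   np.array(d["validation"]), np.array(d["group_labels"]))

    def masks(self, ids: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean row masks for each partition, aligned with `ids`."""
        return {name: np.isin(ids, part) for name, part in
                (("train", self.train), ("test", self.test),
                 ("validation", self.validation))}


def cluster_groups(cohort: Cohort, k: int = 3, seed: int = 0) -> np.ndarray:
    """Assign every record to one of k centroid-based (k-means) groups.

    Clustering runs on a per-feature min-max normalization of the full
    matrix (computed here, used for clustering only) so that wide-range
    metabolite columns do not dominate the Euclidean geometry. Grouping is
    unsupervised and feature-only; labels play no part.
    """
    if k < 1 or k > cohort.n:
        raise ValueError(f"k must lie in [1, {cohort.n}]")
    if k == 1:
        return np.zeros(cohort.n, dtype=int)
    X = cohort.X
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict((X - lo) / span)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items by largest-remainder rounding."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(range(len(fractions)),
                        key=lambda i: (quotas[i] - counts[i], -i),
                        reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def stratified_split(cohort: Cohort, groups: np.ndarray,
                     fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
                     seed: int = 0) -> SplitIndices:
    """Split each group by `fractions` (shuffled, largest-remainder rounded)
    and merge across groups into train/test/validation id sets."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(groups) != cohort.n:
        raise ValueError("group labels length mismatch")
    rng = np.random.default_rng(seed)
    parts: list[list] = [[], [], []]
    for g in np.unique(groups):
        ids = cohort.ids[groups == g]
        ids = ids[rng.permutation(ids.size)]
        counts = _largest_remainder(ids.size, fractions)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(ids[start:start + c].tolist())
            start += c
    return SplitIndices(np.array(parts[0]), np.array(parts[1]),
                        np.array(parts[2]), np.asarray(groups))
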