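"""Mean-replacement sensitivity analysis of a trained predictor.

For each feature in turn, every positive (incident-case) record has that
single feature overwritten by the feature's mean over the non-case
records, the modified records are re-scored by the trained model, and the
mean absolute change in predicted score is recorded. Features whose
replacement moves the predictions most are ranked as most influential.
Replacement happens on the preprocessing (min-max) scale — the scale the
model was trained on; categorical features are replaced by the mean of
their integer codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensitivityReport",
    "nonmi_feature_means",
    "mean_replacement_sensitivity",
    "aggregate_and_rank",
]


@dataclass
class SensitivityReport:
    """Aggregated per-feature influence with ranking and top-k flags."""

    feature_names: list[str]
    mean_change: np.ndarray          # feature-wise mean over replicates
    per_replicate: np.ndarray        # (n_replicates, p)
    rank_order: np.ndarray           # feature indices, most influential first
    top_k: np.ndarray                # boolean flag per feature

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.rank_order]


def nonmi_feature_means(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature mean over the negative (non-case) records."""
    y = np.asarray(y).astype(int).ravel()
    if not np.any(y == 0):
        raise ValueError("need at least one negative record")
    return np.asarray(X, dtype=float)[y == 0].mean(axis=0)


def mean_replacement_sensitivity(model, positive_records: np.ndarray,
                                 means: np.ndarray) -> np.ndarray:
    """Mean |score change| per feature under non-case mean replacement.

    `model` is anything exposing `predict_proba` returning a score per
    record (the package's MlpModel does). Column j of the positive records
    is overwritten with means[j], one feature at a time; all other columns
    stay untouched, so a feature the model provably ignores scores exactly 0.
    """
    positives = np.asarray(positive_records, dtype=float)
    means = np.asarray(means, dtype=float).ravel()
    if positives.shape[0] == 0:
        raise ValueError("positive_records must be nonempty")
    if positives.shape[1] != means.size:
        raise ValueError("means length does not match feature count")
    base = np.asarray(model.predict_proba(positives), dtype=float).ravel()
    changes = np.empty(means.size)
    for j in range(means.size):
        mod = positives.copy()
        mod[:, j] = means[j]
        scores = np.asarray(model.predict_proba(mod), dtype=float).ravel()
        changes[j] = float(np.mean(np.abs(scores - base)))
    return changes


def aggregate_and_rank(per_replicate_reports: list[np.ndarray],
                       feature_names: list[str],
                       top_k: int = 20) -> SensitivityReport:
    """Feature-wise mean over replicates, descending rank, top-k flags.

    Ties are broken by feature name order (ascending), so the ranking is a
    deterministic permutation of all features and invariant under replicate
    order.
    """
    if not per_replicate_reports:
        raise ValueError("need at least one replicate")
    stack = np.vstack([np.asarray(r, dtype=float).ravel()
                       for r in per_replicate_reports])
    if stack.shape[1] != len(feature_names):
        raise ValueError("replicate schema mismatch")
    mean_change = stack.mean(axis=0)
    name_rank = np.argsort(np.argsort(feature_names))
    order = sorted(range(len(feature_names)),
                   key=lambda j: (-mean_change[j], name_rank[j]))
    rank_order = np.array(order)
    flags = np.zeros(len(feature_names), dtype=bool)
    flags[rank_order[:top_k]] = True
    return SensitivityReport(list(feature_names), mean_change, stack,
                             rank_order, flags)
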