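"""Data-cleaning chain for the cohort table.

Order of operations (fixed — the steps do not commute):

1. drop metabolite columns with more than 20% missing values,
2. drop participants missing more than 10% of the remaining metabolites,
3. natural-log transform of metabolite columns (right-skewed, strictly
   positive relative ion counts),
4. chained-equation imputation of the remaining missing cells,
5. per-feature min-max scaling to [0, 1], fitted on a training partition
   and applied everywhere (constant features map to 0, out-of-range values
   are clipped).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cohort import Cohort

__all__ = [
    "filter_metabolites_by_missingness",
    "filter_participants_by_missingness",
    "log_transform_metabolites",
    "impute_chained",
    "Scaler",
    "minmax_fit",
    "minmax_apply",
]

log = logging.getLogger(__name__)


def filter_metabolites_by_missingness(cohort: Cohort,
                                      threshold: float = 0.20) -> Cohort:
    """Drop metabolite columns whose missing fraction is strictly greater
    than `threshold` (default 20%). Clinical columns are never dropped."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    frac = np.isnan(cohort.X).mean(axis=0)
    drop = cohort.metabolite_mask & (frac > threshold)
    if not drop.any():
        return cohort.copy()
    return cohort.take_columns(~drop)


def filter_participants_by_missingness(cohort: Cohort,
                                       threshold: float = 0.10) -> Cohort:
    """Drop rows missing strictly more than `threshold` (default 10%) of the
    metabolite columns; labels and ids are filtered in lockstep."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    met = cohort.metabolite_mask
    if not met.any():
        return cohort.copy()
    frac = np.isnan(cohort.X[:, met]).mean(axis=1)
    return cohort.take_rows(frac <= threshold)


def log_transform_metabolites(cohort: Cohort) -> Cohort:
    """Natural log of metabolite columns only; missing cells stay missing."""
    out = cohort.copy()
    met = out.metabolite_mask
    block = out.X[:, met]
    bad = block <= 0
    bad &= ~np.isnan(block)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        col = np.flatnonzero(met)[c]
        raise ValueError(
            f"non-positive metabolite value at row {cohort.ids[r]!r}, "
            f"column {cohort.meta[col].name!r}")
    out.X[:, met] = np.log(block)
    return out


def impute_chained(cohort: Cohort, n_sweeps: int = 10,
                   seed: int = 0) -> Cohort:
    """Single deterministic chained-equation completion.

    Each incomplete feature is regressed on all the others, sweeping
    `n_sweeps` times from a mean-initialized fill; no posterior draws, so
    the completion is deterministic given the seed. Intended to run after
    the two missingness filters and the log transform.
    """
    if not np.isnan(cohort.X).any():
        return cohort.copy()
    if (~np.isnan(cohort.X)).sum(axis=0).min() == 0:
        j = int(np.argmin((~np.isnan(cohort.X)).sum(axis=0)))
        raise ValueError(
            f"feature {cohort.meta[j].name!r} has no observed values")
    imputer = IterativeImputer(
        max_iter=n_sweeps, initial_strategy="mean", sample_posterior=False,
        random_state=seed, tol=1e-6)
    out = cohort.copy()
    out.X = imputer.fit_transform(out.X)
    return out


@dataclass
class Scaler:
    """Per-feature min/max learned on a fitting partition."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min for some feature")

    def to_json(self, path: str | Path) -> None:
        payload = {name: [float(lo), float(hi)] for name, lo, hi
                   in zip(self.feature_names, self.mins, self.maxs)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scaler":
        payload = json.loads(Path(path).read_text())
        names = list(payload)
        arr = np.array([payload[n] for n in names], dtype=float)
        return cls(names, arr[:, 0], arr[:, 1])

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.mins) / safe
        out = np.where(span > 0, out, 0.0)  # constant feature -> 0
        return np.clip(out, 0.0, 1.0)

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return X * (self.maxs - self.mins) + self.mins


def minmax_fit(cohort_partition: Cohort) -> Scaler:
    if cohort_partition.n == 0:
        raise ValueError("fit partition is empty")
    X = cohort_partition.X
    return Scaler(cohort_partition.feature_names,
                  np.nanmin(X, axis=0), np.nanmax(X, axis=0))


def minmax_apply(scaler: Scaler, cohort: Cohort) -> Cohort:
    if scaler.feature_names != cohort.feature_names:
        raise ValueError("scaler/cohort feature mismatch")
    out = cohort.copy()
    out.X = scaler.transform(out.X)
    return out
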