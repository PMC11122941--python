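"""Synthetic cohort generator.

Emulates the statistical structure of a population-based cardiometabolic
cohort: a participant-by-feature table mixing continuous clinical variables,
integer-coded categorical clinical variables (e.g. sex, physical-activity
level, glucose-tolerance group) and a large panel of right-skewed, strictly
positive metabolite intensities, with a rare binary outcome (incident
myocardial infarction). The default schema matches the study population the
method targets: 1376 non-cases, 78 incident cases, 19 clinical variables and
363 metabolites (382 features in total).

Outcome labels are drawn from a logistic model on a configurable set of
signal features; the intercept is solved numerically so the expected
prevalence equals the requested case fraction, and records are then sampled
until the exact class counts are reached. Categorical variables are kept as
integer codes (no one-hot expansion), matching a downstream network with one
input per feature.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "CohortSpec",
    "FeatureMeta",
    "Cohort",
    "simulate_cohort",
    "inject_missingness",
    "no_signal_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

KIND_CONT = "clinical-continuous"
KIND_CAT = "clinical-categorical"
KIND_MET = "metabolite"

#: categorical level counts for the default schema: sex, smoker, fasting,
#: stroke, statin (binary), glucose tolerance (3), physical activity (4)
_DEFAULT_LEVELS = [2, 2, 2, 2, 2, 3, 4]


def _default_signal() -> list[tuple[int, float]]:
    """Planted log-odds effects for the default schema.

    Clinical signal sits on sex (feature 12), glucose-tolerance group (17)
    and physical activity (18), mirroring the risk factors the outcome is
    known to track; a sparse subset of 10 metabolites carries moderate
    effects on the log scale.
    """
    clinical = [(12, 1.0), (17, 0.6), (18, 0.35)]
    mets = [(19 + 5 * j, 0.45 if j % 2 == 0 else -0.45) for j in range(10)]
    return clinical + mets


@dataclass
class CohortSpec:
    """Configuration of the simulated cohort."""

    n_negative: int = 1376
    n_positive: int = 78
    n_clinical_continuous: int = 12
    n_clinical_categorical: int = 7
    categorical_level_counts: list[int] = field(
        default_factory=lambda: list(_DEFAULT_LEVELS))
    n_metabolites: int = 363
    signal_features: list[tuple[int, float]] = field(
        default_factory=_default_signal)
    metabolite_log_mean_sd: tuple[float, float] = (0.0, 1.0)
    #: latent-factor correlation of the metabolite panel: metabolite panels
    #: measure overlapping pathways, so log-abundances share a modest number
    #: of latent factors rather than varying independently
    n_metabolite_factors: int = 10
    metabolite_factor_share: float = 0.6
    missing_col_rate: float = 0.0
    missing_row_rate: float = 0.0
    seed: int = 0

    @property
    def n_features(self) -> int:
        return (self.n_clinical_continuous + self.n_clinical_categorical
                + self.n_metabolites)

    def validate(self) -> None:
        counts = (self.n_negative, self.n_positive, self.n_clinical_continuous,
                  self.n_clinical_categorical, self.n_metabolites)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if len(self.categorical_level_counts) != self.n_clinical_categorical:
            raise ValueError("categorical_level_counts length mismatch")
        if any(k < 2 for k in self.categorical_level_counts):
            raise ValueError("categorical level counts must be >= 2")
        for idx, coef in self.signal_features:
            if not (0 <= idx < self.n_features):
                raise ValueError(f"signal feature index {idx} out of range")
            if not np.isfinite(coef):
                raise ValueError("signal coefficients must be finite")
        for rate in (self.missing_col_rate, self.missing_row_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("missingness rates must lie in [0, 1]")
        if not (0.0 <= self.metabolite_factor_share <= 1.0):
            raise ValueError("metabolite_factor_share must lie in [0, 1]")
        if self.n_metabolite_factors < 0:
            raise ValueError("n_metabolite_factors must be nonnegative")


@dataclass
class FeatureMeta:
    name: str
    kind: str  # clinical-continuous | clinical-categorical | metabolite
    levels: int | None = None  # level count for categoricals


@dataclass
class Cohort:
    """Participant-by-feature table with labels and per-feature metadata.

    `X` is numeric throughout; categorical clinical variables are integer
    codes, metabolite values are strictly positive where observed, and
    missing cells are NaN.
    """

    ids: np.ndarray            # record identifiers, unique
    X: np.ndarray              # (n, p) float matrix
    y: np.ndarray              # (n,) in {0, 1}; 1 = incident case
    meta: list[FeatureMeta]

    def __post_init__(self):
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate record ids")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if len(self.meta) != self.X.shape[1]:
            raise ValueError("meta length must equal feature count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    def kind_mask(self, kind: str) -> np.ndarray:
        return np.array([m.kind == kind for m in self.meta])

    @property
    def metabolite_mask(self) -> np.ndarray:
        return self.kind_mask(KIND_MET)

    def copy(self) -> "Cohort":
        return Cohort(self.ids.copy(), self.X.copy(), self.y.copy(),
                      [dataclasses.replace(m) for m in self.meta])

    def take_rows(self, idx: np.ndarray) -> "Cohort":
        return Cohort(self.ids[idx], self.X[idx], self.y[idx],
                      [dataclasses.replace(m) for m in self.meta])

    def take_columns(self, keep: np.ndarray) -> "Cohort":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        meta = [dataclasses.replace(self.meta[j]) for j in keep]
        return Cohort(self.ids.copy(), self.X[:, keep], self.y.copy(), meta)


_CONT_NAMES = ["age", "bmi", "whr", "sbp", "dbp", "total_chol", "hdl", "ldl",
               "hba1c", "fasting_glucose", "alcohol", "hscrp"]
_CAT_NAMES = ["sex", "smoker", "fasting", "stroke", "statin",
              "glucose_tolerance", "physical_activity"]


def _default_meta(spec: CohortSpec) -> list[FeatureMeta]:
    meta: list[FeatureMeta] = []
    for j in range(spec.n_clinical_continuous):
        name = _CONT_NAMES[j] if j < len(_CONT_NAMES) else f"clin_cont_{j:02d}"
        meta.append(FeatureMeta(name, KIND_CONT))
    default_names = (_CAT_NAMES
                     if spec.categorical_level_counts == _DEFAULT_LEVELS
                     else [])
    for j, k in enumerate(spec.categorical_level_counts):
        name = default_names[j] if j < len(default_names) else f"clin_cat_{j:02d}"
        meta.append(FeatureMeta(name, KIND_CAT, levels=k))
    for j in range(spec.n_metabolites):
        meta.append(FeatureMeta(f"met_{j:03d}", KIND_MET))
    return meta


class _FeatureSampler:
    """Draws feature rows: continuous ~ N(0,1), categoricals uniform integer
    codes, metabolites log-normal with a latent-factor correlation
    structure (a share of each log-abundance's variance is carried by a
    small number of factors shared across the panel, emulating pathway-level
    co-regulation). Loadings are fixed once per cohort."""

    def __init__(self, spec: CohortSpec, rng: np.random.Generator):
        self.spec = spec
        k, m = spec.n_metabolite_factors, spec.n_metabolites
        if m and k and spec.metabolite_factor_share > 0:
            raw = rng.normal(size=(k, m))
            self.loadings = raw / np.linalg.norm(raw, axis=0)  # unit columns
        else:
            self.loadings = None

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        spec = self.spec
        parts = []
        if spec.n_clinical_continuous:
            parts.append(rng.normal(size=(n, spec.n_clinical_continuous)))
        for k in spec.categorical_level_counts:
            parts.append(rng.integers(0, k, size=(n, 1)).astype(float))
        if spec.n_metabolites:
            mu, sd = spec.metabolite_log_mean_sd
            noise = rng.normal(size=(n, spec.n_metabolites))
            if self.loadings is not None:
                share = spec.metabolite_factor_share
                factors = rng.normal(
                    size=(n, spec.n_metabolite_factors)) @ self.loadings
                z = np.sqrt(share) * factors + np.sqrt(1.0 - share) * noise
            else:
                z = noise
            parts.append(np.exp(mu + sd * z))
        return np.concatenate(parts, axis=1) if parts else np.empty((n, 0))


def _linear_predictor(spec: CohortSpec, X: np.ndarray) -> np.ndarray:
    """Xβ over the signal features; metabolites enter on the log scale."""
    met_start = spec.n_clinical_continuous + spec.n_clinical_categorical
    lp = np.zeros(X.shape[0])
    for idx, coef in spec.signal_features:
        col = X[:, idx]
        if idx >= met_start:
            col = np.log(col)
        lp += coef * col
    return lp


def _solve_intercept(spec: CohortSpec, sampler: _FeatureSampler,
                     rng: np.random.Generator,
                     n_probe: int = 20000) -> float:
    """Intercept b0 with E[sigmoid(b0 + Xβ)] equal to the target prevalence,
    estimated on a probe sample and solved by bracketing."""
    target = spec.n_positive / (spec.n_positive + spec.n_negative)
    if target in (0.0, 1.0):
        return -np.inf if target == 0.0 else np.inf
    lp = _linear_predictor(spec, sampler.draw(n_probe, rng))

    def gap(b0: float) -> float:
        return float(np.mean(special.expit(b0 + lp))) - target

    return optimize.brentq(gap, -40.0, 40.0, xtol=1e-10)


def simulate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Simulate a cohort with exact class counts and planted label signal.

    Labels follow a logistic model on `spec.signal_features`; sampling
    continues in batches until `n_positive` cases and `n_negative` non-cases
    have been collected, so the class counts are exact for every seed.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sampler = _FeatureSampler(spec, rng)
    b0 = _solve_intercept(spec, sampler, rng)

    need_pos, need_neg = spec.n_positive, spec.n_negative
    pos_rows, neg_rows = [], []
    batch = max(2048, need_pos + need_neg)
    guard = 0
    while need_pos > 0 or need_neg > 0:
        X = sampler.draw(batch, rng)
        prob = special.expit(b0 + _linear_predictor(spec, X))
        y = (rng.random(batch) < prob)
        if need_pos > 0:
            take = X[y][:need_pos]
            pos_rows.append(take)
            need_pos -= take.shape[0]
        if need_neg > 0:
            take = X[~y][:need_neg]
            neg_rows.append(take)
            need_neg -= take.shape[0]
        guard += 1
        if guard > 10000:  # unreachable for any sane prevalence
            raise RuntimeError("class-count sampling did not converge")

    X = np.concatenate(
        [np.concatenate(pos_rows) if pos_rows else np.empty((0, spec.n_features)),
         np.concatenate(neg_rows) if neg_rows else np.empty((0, spec.n_features))])
    y = np.concatenate([np.ones(spec.n_positive, dtype=int),
                        np.zeros(spec.n_negative, dtype=int)])
    order = rng.permutation(X.shape[0])
    X, y = X[order], y[order]
    ids = np.array([f"R{i:05d}" for i in range(X.shape[0])])
    cohort = Cohort(ids, X, y, _default_meta(spec))
    if spec.missing_col_rate or spec.missing_row_rate:
        cohort = inject_missingness(cohort, spec)
    return cohort


def inject_missingness(cohort: Cohort, spec: CohortSpec,
                       n_cols: int = 30, n_rows: int = 10) -> Cohort:
    """MCAR missingness on metabolite columns/rows at the spec's rates.

    A random subset of `n_cols` metabolite columns receives cell-level
    missingness at `missing_col_rate`; a disjoint-in-purpose subset of
    `n_rows` records receives missingness across metabolite columns at
    `missing_row_rate`. Clinical columns are never touched.
    """
    for rate in (spec.missing_col_rate, spec.missing_row_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    if spec.missing_col_rate == 0.0 and spec.missing_row_rate == 0.0:
        return cohort
    out = cohort.copy()
    rng = np.random.default_rng(spec.seed + 1)
    met_cols = np.flatnonzero(out.metabolite_mask)
    if spec.missing_col_rate > 0.0 and met_cols.size:
        cols = rng.choice(met_cols, size=min(n_cols, met_cols.size),
                          replace=False)
        for c in cols:
            mask = rng.random(out.n) < spec.missing_col_rate
            out.X[mask, c] = np.nan
    if spec.missing_row_rate > 0.0 and met_cols.size:
        rows = rng.choice(out.n, size=min(n_rows, out.n), replace=False)
        for r in rows:
            mask = rng.random(met_cols.size) < spec.missing_row_rate
            out.X[r, met_cols[mask]] = np.nan
    return out


def no_signal_cohort(n_negative: int, n_positive: int, p: int,
                     seed: int = 0) -> Cohort:
    """Cohort whose features are drawn independently of the label.

    Used to study majority-class collapse of conventional classifiers under
    severe imbalance: with no feature-label association, any accuracy above
    chance on the minority class is spurious. Features mimic the default
    schema proportions (clinical continuous/categorical, then metabolites)
    when p is large enough, else all continuous.
    """
    if n_negative < 1 or n_positive < 1 or p < 1:
        raise ValueError("counts must be >= 1")
    if p >= 30:
        n_cat = len(_DEFAULT_LEVELS)
        n_cont = 12
        spec = CohortSpec(
            n_negative=n_negative, n_positive=n_positive,
            n_clinical_continuous=n_cont, n_clinical_categorical=n_cat,
            categorical_level_counts=list(_DEFAULT_LEVELS),
            n_metabolites=p - n_cont - n_cat,
            signal_features=[], seed=seed)
    else:
        spec = CohortSpec(
            n_negative=n_negative, n_positive=n_positive,
            n_clinical_continuous=p, n_clinical_categorical=0,
            categorical_level_counts=[], n_metabolites=0,
            signal_features=[], seed=seed)
    return simulate_cohort(spec)


# --- CSV + sidecar I/O ------------------------------------------------------

def write_cohort_csv(cohort: Cohort, path: str | Path,
                     provenance: np.ndarray | None = None) -> None:
    """Write `id,label,<features...>` CSV (missing cells empty) and a
    `<name>.meta.json` sidecar listing feature name/kind/levels."""
    path = Path(path)
    df = pd.DataFrame(cohort.X, columns=cohort.feature_names)
    df.insert(0, "label", cohort.y)
    df.insert(0, "id", cohort.ids)
    if provenance is not None:
        df["provenance"] = provenance
    df.to_csv(path, index=False, na_rep="")
    sidecar = [{"name": m.name, "kind": m.kind, "levels": m.levels}
               for m in cohort.meta]
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1))


def read_cohort_csv(path: str | Path) -> Cohort:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    entries = json.loads(meta_path.read_text())
    meta = [FeatureMeta(e["name"], e["kind"], e.get("levels"))
            for e in entries]
    names = [m.name for m in meta]
    return Cohort(df["id"].to_numpy().astype(str),
                  df[names].to_numpy(dtype=float),
                  df["label"].to_numpy(dtype=int), meta)
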