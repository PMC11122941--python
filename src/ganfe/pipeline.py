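"""End-to-end experiment pipeline with a replicate harness.

One replicate = cluster + split the (preprocessed) cohort, train the GAN on
the observed positives of the train+test partitions, generate
feature-enhanced positives, balance with iterative SMOTE+ENN, train the
prediction MLP with the chosen loss, evaluate on test and validation, and
run the mean-replacement sensitivity analysis. The harness repeats this for
`replicates` independent splits (default 10) and reports means over
replicates. The validation partition is never seen by the GAN, the
resampler or MLP training — only final evaluation.

Every stage seed is derived deterministically from the master seed, the
replicate index and a stage tag, so a full run is reproducible bit-for-bit
from (config, master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import preprocess
from .cohort import Cohort, CohortSpec, read_cohort_csv, simulate_cohort
from .gan import ReferenceSets, generate, train_gan
from .partition import cluster_groups, stratified_split
from .resample import OBSERVED, iterative_balance
from .sensitivity import (aggregate_and_rank, mean_replacement_sensitivity,
                          nonmi_feature_means)
from .training import MlpSpec, evaluate, train_mlp

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline", "preprocess_cohort"]

log = logging.getLogger(__name__)


def derive_seed(master: int, *keys) -> int:
    """Deterministic stage seed (< 2^31) from a master seed and tags."""
    ints = [int(master) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    # cohort: either a CSV path or a simulation spec
    input_csv: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    # preprocessing
    metabolite_missing_threshold: float = 0.20
    participant_missing_threshold: float = 0.10
    mice_sweeps: int = 10
    # partitioning
    n_groups: int = 3
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    # GAN
    gan_steps: int = 3000
    gan_lr: float = 0.005
    gan_weight_decay: float = 1e-4
    sigma_z: float = 0.1
    n_generated: int = 2600
    # balancing
    balance_batch: int = 100
    target_majority: int = 1000
    smote_enn_repeats: int = 2
    # prediction MLP
    loss: str = "gfe"
    mlp_epochs: int = 200
    mlp_lr: float = 5e-5
    mlp_weight_decay: float = 1e-4
    mlp_batch_size: int = 64
    # harness
    replicates: int = 10
    sensitivity_top_k: int = 20
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "signal_features" in c:
                c["signal_features"] = [tuple(t) for t in c["signal_features"]]
            d["cohort"] = CohortSpec(**c)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            payload = yaml.safe_load(text)
        except yaml.YAMLError:
            payload = json.loads(text)
        return cls.from_dict(payload or {})

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=str))


def preprocess_cohort(cohort: Cohort, config: PipelineConfig,
                      seed: int) -> Cohort:
    """Split-independent cleaning: filters, log transform, imputation."""
    cohort = preprocess.filter_metabolites_by_missingness(
        cohort, config.metabolite_missing_threshold)
    cohort = preprocess.filter_participants_by_missingness(
        cohort, config.participant_missing_threshold)
    cohort = preprocess.log_transform_metabolites(cohort)
    return preprocess.impute_chained(cohort, config.mice_sweeps, seed=seed)


def _report_to_dict(rep) -> dict:
    return {"confusion": {"tp": rep.tp, "fp": rep.fp,
                          "tn": rep.tn, "fn": rep.fn},
            "acc_positive": rep.acc_positive,
            "acc_negative": rep.acc_negative,
            "balanced_accuracy": rep.balanced_accuracy,
            "sensitivity": rep.sensitivity,
            "accuracy": rep.accuracy}


def run_replicate(clean: Cohort, config: PipelineConfig, replicate: int):
    """One split -> GAN -> balance -> train -> evaluate -> sensitivity."""
    seed = lambda stage: derive_seed(config.master_seed, replicate, stage)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    groups = cluster_groups(clean, k=config.n_groups, seed=seed("cluster"))
    split = stratified_split(clean, groups, config.split_fractions,
                             seed=seed("split"))
    masks = split.masks(clean.ids)
    timings["split"] = time.perf_counter() - t0

    scaler = preprocess.minmax_fit(clean.take_rows(masks["train"]))
    scaled = preprocess.minmax_apply(scaler, clean)
    X, y = scaled.X, scaled.y

    gan_pool = masks["train"] | masks["test"]
    positives = X[gan_pool & (y == 1)]
    refs = ReferenceSets(P=positives, N=X[gan_pool & (y == 0)])

    t0 = time.perf_counter()
    bundle = train_gan(positives, steps=config.gan_steps, lr=config.gan_lr,
                       weight_decay=config.gan_weight_decay,
                       sigma_z=config.sigma_z, seed=seed("gan"))
    generated = generate(bundle, positives, n=config.n_generated,
                         seed=seed("generate"))
    timings["gan"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train_mask = masks["train"]
    balanced = iterative_balance(
        X[train_mask], y[train_mask],
        np.full(int(train_mask.sum()), OBSERVED), generated,
        batch=config.balance_batch, target_majority=config.target_majority,
        repeats=config.smote_enn_repeats, seed=seed("balance"))
    timings["balance"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    observed_mask = balanced.provenance == OBSERVED
    eval_sets = {"test": (X[masks["test"]], y[masks["test"]]),
                 "validation": (X[masks["validation"]], y[masks["validation"]])}
    model, history = train_mlp(
        balanced.X, balanced.y, observed_mask, loss=config.loss,
        bundle=bundle, refs=refs,
        spec=MlpSpec(input_dim=X.shape[1], lr=config.mlp_lr,
                     weight_decay=config.mlp_weight_decay,
                     epochs=config.mlp_epochs,
                     batch_size=config.mlp_batch_size),
        seed=seed("mlp"), eval_sets=eval_sets)
    timings["mlp"] = time.perf_counter() - t0

    reports = {name: evaluate(model, Xe, ye)
               for name, (Xe, ye) in eval_sets.items()}

    means = nonmi_feature_means(X, y)
    changes = mean_replacement_sensitivity(model, X[y == 1], means)

    return {"split": split, "scaler": scaler, "bundle": bundle,
            "balanced": balanced, "model": model, "history": history,
            "reports": reports, "sensitivity": changes,
            "timings": timings, "seeds": {s: seed(s) for s in
                                          ("cluster", "split", "gan",
                                           "generate", "balance", "mlp")}}


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Run the replicate harness and aggregate a machine-readable report.

    A failing replicate is logged with its cause and skipped; the remaining
    replicates proceed. Returns the aggregated report dict; when `out_dir`
    is given, the resolved config and report are written beside each other.
    """
    if config.input_csv:
        cohort = read_cohort_csv(config.input_csv)
    else:
        spec = dataclasses.replace(
            config.cohort, seed=derive_seed(config.master_seed, "cohort"))
        cohort = simulate_cohort(spec)
    clean = preprocess_cohort(cohort, config,
                              seed=derive_seed(config.master_seed, "mice"))

    per_replicate = []
    sens_reports = []
    for r in range(config.replicates):
        try:
            res = run_replicate(clean, config, r)
        except Exception:
            log.exception("replicate %d failed; continuing", r)
            continue
        sens_reports.append(res["sensitivity"])
        per_replicate.append({
            "replicate": r,
            "seeds": res["seeds"],
            "timings": res["timings"],
            "balance_log": res["balanced"].iteration_log,
            "reports": {k: _report_to_dict(v)
                        for k, v in res["reports"].items()},
        })

    def _mean(path_get):
        vals = [path_get(p) for p in per_replicate]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    aggregate = {}
    for part in ("test", "validation"):
        aggregate[part] = {
            key: _mean(lambda p, k=key, pt=part: p["reports"][pt][k])
            for key in ("balanced_accuracy", "acc_positive",
                        "acc_negative", "accuracy")}

    sensitivity = (aggregate_and_rank(sens_reports, clean.feature_names,
                                      top_k=config.sensitivity_top_k)
                   if sens_reports else None)
    report = {
        "config_loss": config.loss,
        "n_replicates_completed": len(per_replicate),
        "replicates": per_replicate,
        "aggregate": aggregate,
        "sensitivity_ranking": (sensitivity.ranked_names()
                                if sensitivity else None),
        "sensitivity_mean_change": (
            {n: float(v) for n, v in zip(clean.feature_names,
                                         sensitivity.mean_change)}
            if sensitivity else None),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_json(out_dir / "config.resolved.json")
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
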