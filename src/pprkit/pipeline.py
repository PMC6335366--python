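"""End-to-end wiring: simulate/load → encode → fuse → select → evaluate.

This module is the library realization of the full study protocol; the
command-line interface is a thin wrapper around it.  A single master seed
deterministically derives every module-level seed by stable hashing, so a
pipeline re-run with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Sequence

import numpy as np

from . import dataset_builder, evaluation, features_ctd188, features_pse, fusion_mrmd
from .errors import ConfigError, ValidationError
from .fusion_mrmd import FeatureMatrix
from .sequence_io import ProteinRecord

METHODS = ("188d", "kmer", "acc", "pseaac")


def derive_seed(master_seed: int, *tokens: object) -> int:
    """A stable sub-seed below 2^31 from the master seed and context tokens."""
    key = json.dumps([int(master_seed), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclasses.dataclass(frozen=True)
class EncoderParams:
    """Per-encoder parameters at the study's stated settings."""

    k: int = 2
    lg: int = 2
    lam: int = 2
    weight: float = 0.05
    pse_mode: str = "chou_normalized"


def encode_records(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    method: str,
    params: EncoderParams = EncoderParams(),
) -> FeatureMatrix:
    """Run one encoder over a record collection and return a labelled matrix."""
    if method not in METHODS:
        raise ConfigError(f"unknown encoder {method!r}; choose from {METHODS}")
    if len(records) != len(labels):
        raise ValidationError("one label per record required")
    if method == "188d":
        schemes = features_ctd188.builtin_groupings()
        names = features_ctd188.feature_names(schemes)
        rows = [features_ctd188.extract_188d(r, schemes).values for r in records]
    elif method == "kmer":
        kp = features_pse.KmerParams(k=params.k)
        names = features_pse.kmer_names(kp.k)
        rows = [features_pse.extract_kmer(r, kp) for r in records]
    elif method == "acc":
        ap = features_pse.ACCParams(lg=params.lg)
        names = features_pse.acc_names(ap)
        rows = [features_pse.extract_acc(r, ap) for r in records]
    else:
        pp = features_pse.PseAACParams(
            lam=params.lam, weight=params.weight,
            mode=features_pse.PseAACMode(params.pse_mode),
        )
        names = features_pse.pseaac_names(pp)
        rows = [features_pse.extract_pc_pseaac(r, pp) for r in records]
    return FeatureMatrix(
        tuple(r.id for r in records), names, np.vstack(rows), np.asarray(labels, dtype=int)
    )


def fuse_methods(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    methods: Sequence[str],
    params: EncoderParams = EncoderParams(),
) -> FeatureMatrix:
    """Encode with each requested method and concatenate the results."""
    if not methods:
        raise ConfigError("at least one encoder required")
    return fusion_mrmd.concatenate(
        [encode_records(records, labels, m, params) for m in methods]
    )


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end protocol needs, seeds included."""

    methods: tuple[str, ...] = ("188d",)
    encoder_params: EncoderParams = EncoderParams()
    selection: str = "none"  # none | fixed_n | auc_scan
    selection_n: int | None = None
    selection_grid: tuple[int, ...] | None = None
    classifier: str = "random_forest"
    classifier_params: dict = dataclasses.field(default_factory=dict)
    n_runs: int = 10
    k_folds: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ConfigError(f"unknown encoder {m!r}")
        if self.selection not in ("none", "fixed_n", "auc_scan"):
            raise ConfigError(f"unknown selection strategy {self.selection!r}")
        if self.n_runs < 1 or self.k_folds < 2:
            raise ConfigError("need n_runs >= 1 and k_folds >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    report: evaluation.EvaluationReport
    runs: tuple[dataset_builder.BalancedRun, ...]
    chosen_columns: tuple[str, ...] | None
    config: PipelineConfig


def run_pipeline(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """The full protocol on a curated positive set and negative pool.

    1. Build ``n_runs`` balanced runs by length-stratified proportional
       negative sampling (all positives retained each run).
    2. Encode every record that any run touches, once, with the configured
       encoders; fuse into a single matrix.
    3. Optionally select features: ``fixed_n`` keeps a rank prefix from an
       MRMD ranking of the first run's matrix; ``auc_scan`` ranks and scans
       every run, then applies the single best-scanning subset to all runs.
    4. Cross-validate the configured classifier on each run and aggregate.
    """
    runs = dataset_builder.make_runs(
        positives, negatives, n_runs=config.n_runs,
        base_seed=derive_seed(config.master_seed, "runs"),
    )
    used_neg_ids = {nid for run in runs for nid in run.negative_ids}
    records = list(positives) + [n for n in negatives if n.id in used_neg_ids]
    labels = [1] * len(positives) + [0] * (len(records) - len(positives))
    matrix = fuse_methods(records, labels, config.methods, config.encoder_params)

    chosen: tuple[str, ...] | None = None
    if config.selection == "fixed_n":
        run_matrix = matrix.subset_instances(runs[0].positive_ids + runs[0].negative_ids)
        ranking = fusion_mrmd.rank_mrmd(run_matrix)
        chosen = fusion_mrmd.select_subset(
            run_matrix, ranking, strategy="fixed_n", n=config.selection_n
        ).chosen_columns
    elif config.selection == "auc_scan":
        best: tuple[float, tuple[str, ...]] | None = None
        for run in runs:
            run_matrix = matrix.subset_instances(run.positive_ids + run.negative_ids)
            ranking = fusion_mrmd.rank_mrmd(run_matrix)
            result = fusion_mrmd.select_subset(
                run_matrix, ranking, strategy="auc_scan",
                grid=config.selection_grid,
                seed=derive_seed(config.master_seed, "select", run.run_index),
            )
            scan_auc = max(auc for _, auc in result.trace)
            if best is None or scan_auc > best[0]:
                best = (scan_auc, result.chosen_columns)
        chosen = best[1]
    if chosen is not None:
        matrix = matrix.select_columns(chosen)

    spec = evaluation.ClassifierSpec(
        kind=config.classifier, hyperparameters=config.classifier_params,
        seed=derive_seed(config.master_seed, "clf"),
    )
    reports = []
    for run in runs:
        run_matrix = matrix.subset_instances(run.positive_ids + run.negative_ids)
        reports.append(
            evaluation.cross_validate(
                run_matrix, spec, k=config.k_folds,
                seed=derive_seed(config.master_seed, "cv", run.run_index),
                run_index=run.run_index,
            )
        )
    report = evaluation.aggregate_runs(reports)
    return PipelineResult(report=report, runs=tuple(runs), chosen_columns=chosen,
                          config=config)
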