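"""Cross-validated classifier evaluation: AUC and F-measure.

Classifier training is delegated to scikit-learn behind a small
:class:`ClassifierSpec` contract — the toolkit's own code is the protocol
around them: stratified folds, continuous-score AUC, F-measure, per-run and
cross-run aggregation with full seed provenance.  The decision-tree kind is
an information-gain (entropy) tree, a close but not exact analogue of
C4.5's gain-ratio trees with confidence pruning.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .dataset_builder import kfold_indices
from .errors import UndefinedMetricError, ValidationError
from .fusion_mrmd import FeatureMatrix

CLASSIFIER_KINDS = ("random_forest", "decision_tree", "naive_bayes")


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train and with what hyperparameters.

    Random-forest hyperparameters: ``n_trees`` (default 100), ``max_depth``
    (default unlimited), ``max_features`` per split (default sqrt).
    """

    kind: str = "random_forest"
    hyperparameters: Mapping[str, object] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(
                f"classifier kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    def build(self):
        """Instantiate the backing scikit-learn estimator."""
        hp = self.hyperparameters
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(hp.get("n_trees", 100)),
                max_depth=hp.get("max_depth"),
                max_features=hp.get("max_features", "sqrt"),
                random_state=self.seed,
            )
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(criterion="entropy", random_state=self.seed)
        return GaussianNB()


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula, ties
    counted half; equals the probability a random positive outranks a
    random negative, and the trapezoidal area under the (FPR, TPR) curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f_measure(counts: ConfusionCounts, alpha: float = 1.0) -> float:
    """Weighted harmonic mean of precision and recall,
    F = (alpha^2 + 1) P R / (alpha^2 P + R); F1 at alpha = 1."""
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        return 0.0
    return (alpha**2 + 1) * precision * recall / (alpha**2 * precision + recall)


def weighted_f_measure(counts: ConfusionCounts, alpha: float = 1.0) -> float:
    """Support-weighted mean of the per-class F-measures (the convention
    WEKA-style toolkits report for imbalanced data)."""
    f_pos = f_measure(counts, alpha)
    flipped = ConfusionCounts(tp=counts.tn, fp=counts.fn, fn=counts.fp, tn=counts.tp)
    f_neg = f_measure(flipped, alpha)
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    return (f_pos * n_pos + f_neg * n_neg) / (n_pos + n_neg)


def _f_or_zero(counts: ConfusionCounts, alpha: float = 1.0) -> float:
    """Fold-level F: 0.0 when no positives were predicted (the conventional
    limit), rather than aborting the whole cross-validation."""
    if counts.tp + counts.fp == 0 or counts.tp + counts.fn == 0:
        return 0.0
    return f_measure(counts, alpha)


def _weighted_f_or_zero(counts: ConfusionCounts, alpha: float = 1.0) -> float:
    flipped = ConfusionCounts(tp=counts.tn, fp=counts.fn, fn=counts.fp, tn=counts.tp)
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    return (_f_or_zero(counts, alpha) * n_pos + _f_or_zero(flipped, alpha) * n_neg) / (
        n_pos + n_neg
    )


@dataclasses.dataclass(frozen=True)
class FoldResult:
    fold_index: int
    auc: float
    f1: float
    f1_weighted: float
    counts: ConfusionCounts


@dataclasses.dataclass(frozen=True)
class RunReport:
    """Metrics of one k-fold cross-validation over one (balanced) dataset."""

    run_index: int
    folds: tuple[FoldResult, ...]
    spec: ClassifierSpec
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([f.f1 for f in self.folds]))

    @property
    def mean_f1_weighted(self) -> float:
        return float(np.mean([f.f1_weighted for f in self.folds]))


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    """Cross-run aggregation: per-run means plus their mean and population SD."""

    runs: tuple[RunReport, ...]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValidationError("report needs at least one run")

    def _stat(self, attr: str) -> tuple[float, float]:
        values = np.array([getattr(r, attr) for r in self.runs])
        return float(values.mean()), float(values.std())

    @property
    def mean_auc(self) -> float:
        return self._stat("mean_auc")[0]

    @property
    def sd_auc(self) -> float:
        return self._stat("mean_auc")[1]

    @property
    def mean_f1(self) -> float:
        return self._stat("mean_f1")[0]

    @property
    def sd_f1(self) -> float:
        return self._stat("mean_f1")[1]

    @property
    def mean_f1_weighted(self) -> float:
        return self._stat("mean_f1_weighted")[0]


def cross_validate(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    run_index: int = 1,
    threshold: float = 0.5,
) -> RunReport:
    """Stratified k-fold cross-validation of one classifier on one matrix.

    Each fold trains on k-1 parts, scores the held-out part with the
    positive-class probability, and records AUC plus F-measures from the
    confusion counts at the given score threshold.  Reproducible from
    (seed, spec.seed)."""
    y = matrix.labels
    folds = kfold_indices(matrix.n_instances, k=k, stratified=True, seed=seed, labels=y)
    all_idx = np.arange(matrix.n_instances)
    results = []
    for fold_index, test_idx in enumerate(folds, start=1):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(set(y[train_idx].tolist())) < 2:
            raise UndefinedMetricError(f"fold {fold_index}: single-class training split")
        clf = spec.build()
        clf.fit(matrix.values[train_idx], y[train_idx])
        proba = clf.predict_proba(matrix.values[test_idx])
        scores = proba[:, list(clf.classes_).index(1)]
        y_test = y[test_idx]
        predicted = (scores >= threshold).astype(int)
        counts = ConfusionCounts(
            tp=int(np.sum((predicted == 1) & (y_test == 1))),
            fp=int(np.sum((predicted == 1) & (y_test == 0))),
            fn=int(np.sum((predicted == 0) & (y_test == 1))),
            tn=int(np.sum((predicted == 0) & (y_test == 0))),
        )
        results.append(
            FoldResult(
                fold_index=fold_index,
                auc=roc_auc(scores, y_test),
                f1=_f_or_zero(counts),
                f1_weighted=_weighted_f_or_zero(counts),
                counts=counts,
            )
        )
    return RunReport(run_index=run_index, folds=tuple(results), spec=spec, seed=seed)


def aggregate_runs(reports: Sequence[RunReport]) -> EvaluationReport:
    """Average per-run metrics across balanced runs; SD is the population
    standard deviation over runs (0 for a single run)."""
    if not reports:
        raise ValidationError("no runs to aggregate")
    k = len(reports[0].folds)
    for r in reports[1:]:
        if len(r.folds) != k:
            raise ValidationError("runs disagree on fold count; cannot aggregate")
    return EvaluationReport(tuple(reports))


# ---------------------------------------------------------------------------
# Serialization


def report_to_frame(report: EvaluationReport):
    """Flatten a report to one row per (run, fold)."""
    import pandas as pd

    rows = []
    for run in report.runs:
        for fold in run.folds:
            rows.append(
                {
                    "run": run.run_index,
                    "fold": fold.fold_index,
                    "auc": fold.auc,
                    "f1": fold.f1,
                    "f1_weighted": fold.f1_weighted,
                    "tp": fold.counts.tp,
                    "fp": fold.counts.fp,
                    "fn": fold.counts.fn,
                    "tn": fold.counts.tn,
                }
            )
    return pd.DataFrame(rows)


def summary_text(report: EvaluationReport) -> str:
    """Human-readable cross-run summary."""
    lines = [
        f"runs: {len(report.runs)}   folds/run: {len(report.runs[0].folds)}",
        f"classifier: {report.runs[0].spec.kind}",
        f"mean AUC: {report.mean_auc:.4f}  (SD {report.sd_auc:.4f})",
        f"mean F1 (positive class): {report.mean_f1:.4f}  (SD {report.sd_f1:.4f})",
        f"mean F1 (class-weighted): {report.mean_f1_weighted:.4f}",
    ]
    return "\n".join(lines) + "\n"


def roc_points(scores: Sequence[float], labels: Sequence[int]):
    """(FPR, TPR) pairs of the empirical ROC curve, for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])
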