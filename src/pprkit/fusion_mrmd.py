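"""Feature fusion and Max-Relevance-Max-Distance (MRMD) feature selection.

Fusion concatenates encoder outputs for the same instances into one labelled
matrix.  MRMD then scores each feature by

* **relevance** MR_i = |Pearson(feature_i, class labels)|, and
* **non-redundancy** MD_i = the mean Euclidean distance from feature_i to
  every other feature column (columns min-max scaled first, then the MD
  values divided by their maximum so both terms live on [0, 1]),

ranks features by MR_i + MD_i descending, and selects either a fixed-size
rank prefix or — mirroring the study protocol — the prefix size whose
internal cross-validated AUC is highest.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    AlignmentError,
    EmptyInputError,
    UndefinedMetricError,
    ValidationError,
)


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    """Instances x named features with binary class labels."""

    instance_ids: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray  # shape (n_instances, n_features)
    labels: np.ndarray  # shape (n_instances,), values in {0, 1}

    def __post_init__(self) -> None:
        ids = tuple(self.instance_ids)
        names = tuple(self.names)
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        n, m = len(ids), len(names)
        if values.shape != (n, m):
            raise ValidationError(
                f"values shape {values.shape} does not match {n} instances x {m} features"
            )
        if labels.shape != (n,):
            raise ValidationError("labels must be one value per instance")
        if len(set(ids)) != n:
            raise ValidationError("instance ids must be unique")
        if len(set(names)) != m:
            raise ValidationError("feature names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValidationError("feature values must be finite")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValidationError("labels must be binary (0/1)")
        object.__setattr__(self, "instance_ids", ids)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        """A new matrix restricted to ``names``, in the given order."""
        pos = {n: i for i, n in enumerate(self.names)}
        idx = [pos[n] for n in names]
        return FeatureMatrix(self.instance_ids, tuple(names), self.values[:, idx], self.labels)

    def subset_instances(self, ids: Sequence[str]) -> "FeatureMatrix":
        """A new matrix restricted to the given instances, in the given order."""
        pos = {r: i for i, r in enumerate(self.instance_ids)}
        idx = [pos[r] for r in ids]
        return FeatureMatrix(tuple(ids), self.names, self.values[idx], self.labels[idx])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.names))
        frame.insert(0, "id", list(self.instance_ids))
        frame["label"] = self.labels
        return frame


@dataclasses.dataclass(frozen=True)
class MRMDRanking:
    """Per-feature relevance, distance, combined score, and rank order."""

    names: tuple[str, ...]
    mr: np.ndarray
    md: np.ndarray
    order: tuple[str, ...]  # names sorted by mr+md descending, stable ties

    @property
    def score(self) -> np.ndarray:
        return self.mr + self.md


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    """Chosen feature subset (always a rank prefix) plus the decision trace."""

    chosen_columns: tuple[str, ...]
    strategy: str
    trace: tuple[tuple[int, float], ...]  # (candidate size, criterion value)


def concatenate(feature_sets: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Fuse feature sets covering the same instances into one matrix.

    Instance order, ids, and labels must agree across sets; combined feature
    names must be unique (encoders prefix their names, so fusing distinct
    encoders is always safe)."""
    if not feature_sets:
        raise EmptyInputError("no feature sets to concatenate")
    first = feature_sets[0]
    if first.n_features == 0:
        raise EmptyInputError("feature set 0 has no columns")
    for i, fs in enumerate(feature_sets[1:], start=1):
        if fs.n_features == 0:
            raise EmptyInputError(f"feature set {i} has no columns")
        if fs.instance_ids != first.instance_ids:
            raise AlignmentError(f"feature set {i} covers different instances")
        if not np.array_equal(fs.labels, first.labels):
            raise AlignmentError(f"feature set {i} carries different labels")
    names = tuple(n for fs in feature_sets for n in fs.names)
    values = np.hstack([fs.values for fs in feature_sets])
    return FeatureMatrix(first.instance_ids, names, values, first.labels)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("pearson needs two equal-length vectors of length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0.0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    return float(np.clip(dx @ dy / denom, -1.0, 1.0))


def max_relevance(matrix: FeatureMatrix) -> np.ndarray:
    """MR_i = |Pearson(column_i, labels)|; constant columns get 0 with a warning."""
    labels = matrix.labels
    if len(set(labels.tolist())) < 2:
        raise UndefinedMetricError("relevance requires both classes in the labels")
    mr = np.empty(matrix.n_features)
    constant = []
    for i in range(matrix.n_features):
        column = matrix.values[:, i]
        if np.ptp(column) == 0.0:
            constant.append(matrix.names[i])
            mr[i] = 0.0
        else:
            mr[i] = abs(pearson(column, labels))
    if constant:
        warnings.warn(
            f"{len(constant)} constant feature(s) assigned relevance 0: "
            + ", ".join(constant[:5]),
            stacklevel=2,
        )
    return mr


def _minmax_columns(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=0)
    span = np.ptp(values, axis=0)
    span = np.where(span == 0.0, 1.0, span)
    return (values - lo) / span


def mean_distance(matrix: FeatureMatrix) -> np.ndarray:
    """MD_i = mean Euclidean distance from column i to every other column,
    computed on min-max scaled columns and normalized so max(MD) = 1."""
    if matrix.n_features < 2:
        raise ValidationError("mean_distance needs at least 2 features")
    scaled = _minmax_columns(matrix.values)
    dist = squareform(pdist(scaled.T, metric="euclidean"))
    md = dist.sum(axis=1) / (matrix.n_features - 1)
    top = md.max()
    return md / top if top > 0 else md


def rank_mrmd(matrix: FeatureMatrix) -> MRMDRanking:
    """Rank all features by MR_i + MD_i descending; ties keep column order."""
    mr = max_relevance(matrix)
    md = mean_distance(matrix)
    score = mr + md
    order_idx = np.argsort(-score, kind="stable")
    return MRMDRanking(
        names=matrix.names,
        mr=mr,
        md=md,
        order=tuple(matrix.names[i] for i in order_idx),
    )


def select_subset(
    matrix: FeatureMatrix,
    ranking: MRMDRanking,
    strategy: str = "auc_scan",
    n: int | None = None,
    grid: Sequence[int] | None = None,
    seed: int = 0,
    cv_folds: int = 5,
    classifier=None,
) -> SelectionResult:
    """Choose a rank-prefix feature subset.

    ``fixed_n`` returns the top-n ranked features.  ``auc_scan`` evaluates
    each candidate prefix size in ``grid`` with seeded stratified
    cross-validation of an internal classifier (random forest by default)
    and keeps the size with the highest mean AUC, preferring the smaller
    size on ties."""
    if strategy == "fixed_n":
        if n is None or not 1 <= n <= matrix.n_features:
            raise ValidationError(f"fixed_n needs 1 <= n <= {matrix.n_features}")
        chosen = ranking.order[:n]
        return SelectionResult(tuple(chosen), "fixed_n", ((n, float("nan")),))
    if strategy != "auc_scan":
        raise ValidationError(f"unknown strategy {strategy!r}")

    from .evaluation import ClassifierSpec, cross_validate

    if grid is None:
        grid = sorted({max(1, round(matrix.n_features * f)) for f in
                       (0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0)})
    grid = [int(g) for g in grid]
    if not grid:
        raise ValidationError("auc_scan needs a non-empty size grid")
    if any(not 1 <= g <= matrix.n_features for g in grid):
        raise ValidationError("grid sizes must lie in [1, n_features]")
    spec = classifier or ClassifierSpec(kind="random_forest",
                                        hyperparameters={"n_trees": 50}, seed=seed)
    trace: list[tuple[int, float]] = []
    for size in grid:
        sub = matrix.select_columns(ranking.order[:size])
        report = cross_validate(sub, spec, k=cv_folds, seed=seed)
        trace.append((size, report.mean_auc))
    best_size, _ = max(trace, key=lambda t: (t[1], -t[0]))
    return SelectionResult(tuple(ranking.order[:best_size]), "auc_scan", tuple(trace))


# ---------------------------------------------------------------------------
# Delimited-text and ARFF persistence


def write_matrix(matrix: FeatureMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index=False)


def read_matrix(path: str | Path, sep: str = "\t") -> FeatureMatrix:
    frame = pd.read_csv(path, sep=sep)
    if frame.columns[0] != "id" or frame.columns[-1] != "label":
        raise ValidationError(
            f"{path}: expected first column 'id' and last column 'label'"
        )
    names = tuple(frame.columns[1:-1])
    return FeatureMatrix(
        tuple(str(i) for i in frame["id"]),
        names,
        frame[list(names)].to_numpy(dtype=float),
        frame["label"].to_numpy(dtype=int),
    )


def write_arff(matrix: FeatureMatrix, path: str | Path, relation: str = "pprkit") -> None:
    """Write the matrix in ARFF for interoperability with WEKA-style tools."""
    with open(path, "w") as handle:
        handle.write(f"@RELATION {relation}\n\n")
        for name in matrix.names:
            safe = name.replace(" ", "_")
            handle.write(f"@ATTRIBUTE {safe} NUMERIC\n")
        handle.write("@ATTRIBUTE class {0,1}\n\n@DATA\n")
        for row, label in zip(matrix.values, matrix.labels):
            handle.write(",".join(f"{v:.10g}" for v in row) + f",{label}\n")
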