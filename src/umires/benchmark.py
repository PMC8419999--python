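"""Pipeline grid for cell-type separation: HVG selection x transform ->
PCA -> leave-one-out kNN -> macro F1.

Macro F1 (the unweighted mean of per-class F1) is used because it is
sensitive to the rare class, unlike overall accuracy.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from umires.count_model import (
    DEFAULT_THETA,
    CountMatrix,
    deviance_residuals,
    pearson_residuals,
)
from umires.hvg import SCORE_METHODS, score_genes, select_top_k
from umires.synthetic_data import LabeledDataset
from umires.transforms import depth_normalize, log_family, sqrt_family, standardize

logger = logging.getLogger(__name__)

TRANSFORMS = (
    "pearson",
    "deviance",
    "sqrt_cpmedian",
    "log_cpmedian",
    "log_cpmedian_std",
    "log_cpm",
)

HVG_METHODS = SCORE_METHODS + ("none",)


@dataclasses.dataclass(frozen=True)
class PipelineSpec:
    """One normalization pipeline: gene selection, transform, reduction."""

    hvg_method: str = "pearson_var"
    n_hvgs: int = 2000
    transform: str = "pearson"
    theta: float = DEFAULT_THETA
    n_components: int = 50

    def __post_init__(self) -> None:
        if self.hvg_method not in HVG_METHODS:
            raise ValueError(f"unknown HVG method {self.hvg_method!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def name(self) -> str:
        return f"{self.hvg_method}+{self.transform}"


@dataclasses.dataclass
class BenchmarkResult:
    """Evaluation of one pipeline on a labeled dataset."""

    pipeline: PipelineSpec
    macro_f1: float
    accuracy: float
    per_class: pd.DataFrame
    predictions: np.ndarray
    error: str | None = None


def transform_matrix(X: CountMatrix, transform: str, theta: float = DEFAULT_THETA) -> np.ndarray:
    """Apply a named data transformation, returning a dense cell x gene matrix."""
    if transform == "pearson":
        return pearson_residuals(X, theta=theta, clip="sqrt_n").values
    if transform == "deviance":
        return deviance_residuals(X, theta=theta).values
    if transform == "sqrt_cpmedian":
        return sqrt_family(depth_normalize(X, "median"), "sqrt")
    if transform == "log_cpmedian":
        return log_family(depth_normalize(X, "median"), 1.0)
    if transform == "log_cpmedian_std":
        return standardize(log_family(depth_normalize(X, "median"), 1.0))
    if transform == "log_cpm":
        return log_family(depth_normalize(X, "million"), 1.0)
    raise ValueError(f"unknown transform {transform!r}")


def reduce(M: np.ndarray, n_components: int = 50) -> np.ndarray:
    """PCA scores with a deterministic sign convention.

    Each component is oriented so that its largest-magnitude loading is
    positive.
    """
    M = np.asarray(M, dtype=float)
    if n_components > min(M.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix shape)={min(M.shape)}"
        )
    pca = PCA(n_components=n_components, random_state=0)
    scores = pca.fit_transform(M)
    for j in range(n_components):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def knn_loo_predict(E: np.ndarray, labels, k: int = 15) -> np.ndarray:
    """Leave-one-out k-nearest-neighbor majority-vote predictions.

    Euclidean distances; the cell itself is excluded from its neighbors;
    vote ties go to the smallest class label (lexicographic).
    """
    E = np.asarray(E, dtype=float)
    labels = np.asarray(labels)
    n = E.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    _, idx = nn.kneighbors(E)
    pred = np.empty(n, dtype=int)
    for i in range(n):
        nbr = idx[i][idx[i] != i][:k]
        votes = np.bincount(y[nbr], minlength=classes.size)
        pred[i] = votes.argmax()  # first max = smallest class label
    return classes[pred]


def per_class_scores(true_labels, predicted_labels) -> pd.DataFrame:
    """Per-class precision, recall, and F1; classes taken from the true labels."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0:
        raise ValueError("empty input")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label arrays must have equal length")
    classes = np.unique(true_labels)
    rows = []
    for c in classes:
        tp = np.sum((true_labels == c) & (predicted_labels == c))
        fp = np.sum((true_labels != c) & (predicted_labels == c))
        fn = np.sum((true_labels == c) & (predicted_labels != c))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {"class": c, "precision": precision, "recall": recall, "f1": f1}
        )
    return pd.DataFrame(rows)


def macro_f1(true_labels, predicted_labels) -> float:
    """Unweighted mean of per-class F1 over the classes present in the truth."""
    return float(per_class_scores(true_labels, predicted_labels)["f1"].mean())


def evaluate_pipeline(
    dataset: LabeledDataset, pipeline: PipelineSpec, k: int = 15
) -> BenchmarkResult:
    """Run one pipeline end to end on a labeled dataset.

    When HVG selection precedes the transform, sequencing depths inside the
    transform are recomputed over the selected genes only (the count matrix
    is subset before the transform sees it).
    """
    X = dataset.counts
    if pipeline.hvg_method != "none":
        scores = score_genes(X, pipeline.hvg_method, theta=pipeline.theta)
        n_hvgs = min(pipeline.n_hvgs, X.n_genes)
        X = X.subset_genes(select_top_k(scores, n_hvgs))
    M = transform_matrix(X, pipeline.transform, theta=pipeline.theta)
    E = reduce(M, pipeline.n_components)
    pred = knn_loo_predict(E, dataset.labels, k=k)
    table = per_class_scores(dataset.labels, pred)
    return BenchmarkResult(
        pipeline=pipeline,
        macro_f1=float(table["f1"].mean()),
        accuracy=float(np.mean(pred == dataset.labels)),
        per_class=table,
        predictions=pred,
    )


def default_grid(
    n_hvgs: int = 2000, theta: float = DEFAULT_THETA, n_components: int = 50
) -> list[PipelineSpec]:
    """The in-scope grid: 6 transforms x (5 HVG methods + none)."""
    return [
        PipelineSpec(
            hvg_method=h,
            n_hvgs=n_hvgs,
            transform=t,
            theta=theta,
            n_components=n_components,
        )
        for h in HVG_METHODS
        for t in TRANSFORMS
    ]


def run_grid(
    dataset: LabeledDataset, pipelines: list[PipelineSpec], k: int = 15
) -> pd.DataFrame:
    """Evaluate every pipeline; failures are recorded per row and the grid
    continues.  Returns one row per pipeline with per-class F1 columns."""
    rows = []
    for pipe in pipelines:
        t0 = time.perf_counter()
        row = {
            "pipeline": pipe.name,
            "hvg_method": pipe.hvg_method,
            "transform": pipe.transform,
            "n_hvgs": pipe.n_hvgs,
            "theta": pipe.theta,
            "n_components": pipe.n_components,
        }
        try:
            res = evaluate_pipeline(dataset, pipe, k=k)
        except Exception as exc:  # noqa: BLE001 - grid must continue
            row.update({"macro_f1": np.nan, "accuracy": np.nan, "error": str(exc)})
        else:
            row.update({"macro_f1": res.macro_f1, "accuracy": res.accuracy, "error": ""})
            for _, r in res.per_class.iterrows():
                row[f"f1_{r['class']}"] = r["f1"]
                row[f"recall_{r['class']}"] = r["recall"]
        row["seconds"] = time.perf_counter() - t0
        logger.info("pipeline %s: %.1fs", pipe.name, row["seconds"])
        rows.append(row)
    return pd.DataFrame(rows)
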