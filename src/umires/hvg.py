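"""Highly-variable-gene selection and gene filtering.

Genes are scored by the per-gene variance after a chosen transformation
(clipped Pearson residuals by default) and the top-k scorers are selected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from umires.count_model import (
    DEFAULT_THETA,
    CountMatrix,
    residual_variance,
)
from umires.transforms import depth_normalize, fano_factor, log_family, sqrt_family

logger = logging.getLogger(__name__)

SCORE_METHODS = ("pearson_var", "deviance_var", "sqrt_var", "log_var", "fano")


def filter_min_cells(X: CountMatrix, min_cells: int = 5) -> CountMatrix:
    """Remove genes detected (count > 0) in fewer than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    n_expressing = np.asarray((X.counts > 0).sum(axis=0)).ravel()
    keep = np.flatnonzero(n_expressing >= min_cells)
    if keep.size == 0:
        raise ValueError(f"no genes detected in at least {min_cells} cells")
    removed = X.n_genes - keep.size
    if removed:
        logger.info("filter_min_cells removed %d of %d genes", removed, X.n_genes)
    return X.subset_genes(keep)


def score_genes(
    X: CountMatrix,
    method: str = "pearson_var",
    theta: float = DEFAULT_THETA,
    clip="sqrt_n",
) -> np.ndarray:
    """Per-gene selection scores (higher = more variable).

    ``pearson_var`` uses clipped Pearson residuals by default, which keeps
    very weakly expressed genes from dominating; ``deviance_var`` is
    unclipped, matching how deviance residuals are used downstream.
    """
    if method == "pearson_var":
        return residual_variance(X, kind="pearson", theta=theta, clip=clip)
    if method == "deviance_var":
        return residual_variance(X, kind="deviance", theta=theta, clip=None)
    if method == "sqrt_var":
        return sqrt_family(depth_normalize(X, "median"), "sqrt").var(axis=0)
    if method == "log_var":
        return log_family(depth_normalize(X, "median"), 1.0).var(axis=0)
    if method == "fano":
        return fano_factor(X)
    raise ValueError(f"unknown scoring method {method!r}; expected one of {SCORE_METHODS}")


def select_top_k(scores, k: int) -> np.ndarray:
    """Indices (sorted ascending) of the k largest scores.

    Ties are broken by ascending gene index so selection is deterministic and
    invariant to permutations up to this rule.
    """
    scores = np.asarray(scores, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > scores.size:
        raise ValueError(f"k={k} exceeds the number of genes ({scores.size})")
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def score_table(
    X: CountMatrix,
    method: str = "pearson_var",
    n_top: int | None = None,
    theta: float = DEFAULT_THETA,
    clip="sqrt_n",
) -> pd.DataFrame:
    """Score table (gene_id, mean, score, selected) reproducible from k alone."""
    scores = score_genes(X, method, theta=theta, clip=clip)
    mean = np.asarray(X.counts.mean(axis=0)).ravel()
    selected = np.zeros(X.n_genes, dtype=bool)
    if n_top is not None:
        selected[select_top_k(scores, n_top)] = True
    return pd.DataFrame(
        {
            "gene_id": X.gene_ids,
            "mean_expression": mean,
            "score": scores,
            "selected": selected,
        }
    )
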