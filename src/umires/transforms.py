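"""Competitor normalizations: depth scaling, square-root and log families,
per-gene standardization, and the Fano factor."""

from __future__ import annotations

import warnings

import numpy as np

from umires.count_model import CountMatrix, sequencing_depths


def median_depth(X: CountMatrix) -> float:
    """Median sequencing depth; the lower median for an even cell count."""
    depths = np.sort(sequencing_depths(X))
    return float(depths[(len(depths) - 1) // 2])


def depth_normalize(X: CountMatrix, scale="median") -> np.ndarray:
    """Divide each cell by its depth and rescale by a common factor.

    ``scale`` is ``"median"`` (median depth across cells, lower median),
    ``"million"`` (counts per million), or a positive constant.  Returns a
    dense float matrix; zeros are preserved exactly.
    """
    depths = sequencing_depths(X).astype(float)
    if np.any(depths == 0):
        cell = X.cell_ids[int(np.argmin(depths))]
        raise ValueError(f"cell {cell!r} has zero sequencing depth")
    if scale == "median":
        s = median_depth(X)
    elif scale == "million":
        s = 1e6
    else:
        s = float(scale)
        if s <= 0:
            raise ValueError("scale constant must be positive")
    return X.to_dense() * (s / depths)[:, None]


_SQRT_VARIANTS = ("sqrt", "anscombe", "freeman_tukey")


def sqrt_family(Y, variant: str = "sqrt") -> np.ndarray:
    """Square-root-type variance-stabilizing transforms, elementwise.

    sqrt(y); Anscombe 2*sqrt(y + 3/8); Freeman-Tukey sqrt(y) + sqrt(y + 1).
    """
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("square-root transforms require nonnegative input")
    if variant == "sqrt":
        return np.sqrt(Y)
    if variant == "anscombe":
        return 2.0 * np.sqrt(Y + 0.375)
    if variant == "freeman_tukey":
        return np.sqrt(Y) + np.sqrt(Y + 1.0)
    raise ValueError(f"unknown variant {variant!r}; expected one of {_SQRT_VARIANTS}")


def log_family(Y, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise ln(y + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("log transform requires nonnegative input")
    return np.log(Y + pseudocount)


def standardize(M) -> np.ndarray:
    """Center each gene (column) at 0 and scale to unit population variance.

    Zero-variance genes are mapped to 0 (a warning is emitted).
    """
    M = np.asarray(M, dtype=float)
    mean = M.mean(axis=0)
    var = M.var(axis=0)
    zero = var == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance genes mapped to 0")
    out = (M - mean) / np.sqrt(np.where(zero, 1.0, var))
    out[:, zero] = 0.0
    return out


def fano_factor(X: CountMatrix) -> np.ndarray:
    """Per-gene variance/mean ratio of median-normalized counts.

    Zero-mean genes get the value 0.
    """
    Y = depth_normalize(X, scale="median")
    mean = Y.mean(axis=0)
    var = Y.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = var / mean
    return np.where(mean > 0, fano, 0.0)
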