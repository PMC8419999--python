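"""Closed-form rank-one null model for UMI counts and its residuals.

The null model assumes that every gene takes up a fixed fraction ``p_g`` of
each cell's total UMI count ``n_c``, so the expected count is
``mu_cg = n_c * p_g``.  Under a Poisson noise model the maximum-likelihood
estimates of ``n_c`` and ``p_g`` are simply the matrix margins, which makes
the fit, the Pearson residuals

    Z_cg = (X_cg - mu_cg) / sqrt(mu_cg + mu_cg**2 / theta)

and the deviance residuals available in closed form.  ``theta`` is a shared
negative-binomial overdispersion parameter; ``theta = POISSON`` (infinity)
selects the pure Poisson model.

Cells are rows and genes are columns everywhere in this package.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import xlogy

#: Sentinel overdispersion value selecting the Poisson model (theta -> inf).
#: All arithmetic branches on ``is_poisson(theta)`` rather than relying on
#: floating-point infinity propagating through formulas.
POISSON = math.inf

#: Default shared overdispersion, appropriate for droplet UMI data.
DEFAULT_THETA = 100.0


def is_poisson(theta: float) -> bool:
    """True if ``theta`` is the Poisson sentinel (infinite overdispersion)."""
    return math.isinf(theta)


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if math.isnan(theta) or theta <= 0:
        raise ValueError(f"theta must be positive or infinite, got {theta}")
    return theta


@dataclasses.dataclass
class CountMatrix:
    """Sparse cell-by-gene matrix of nonnegative integer UMI counts.

    Parameters
    ----------
    counts
        Any scipy-sparse or dense array-like; stored as CSR internally.
    cell_ids, gene_ids
        Row / column identifiers; lengths must match the matrix shape.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        X = sp.csr_matrix(self.counts)
        if X.nnz:
            data = X.data
            if np.any(data < 0):
                raise ValueError("count matrix contains negative entries")
            if np.any(data != np.floor(data)):
                raise ValueError("count matrix contains non-integral entries")
        self.counts = X
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if len(self.cell_ids) != X.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {X.shape[0]} matrix rows"
            )
        if len(self.gene_ids) != X.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {X.shape[1]} matrix columns"
            )

    @classmethod
    def from_dense(
        cls,
        array,
        cell_ids: Sequence[str] | None = None,
        gene_ids: Sequence[str] | None = None,
    ) -> "CountMatrix":
        array = np.asarray(array)
        if array.ndim != 2:
            raise ValueError("expected a 2-d array")
        n_cells, n_genes = array.shape
        if cell_ids is None:
            cell_ids = [f"cell{i}" for i in range(n_cells)]
        if gene_ids is None:
            gene_ids = [f"gene{j}" for j in range(n_genes)]
        return cls(sp.csr_matrix(array), list(cell_ids), list(gene_ids))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given gene indices."""
        index = np.asarray(index)
        return CountMatrix(
            self.counts[:, index].tocsr(),
            self.cell_ids,
            [self.gene_ids[j] for j in index],
        )


def sequencing_depths(X: CountMatrix) -> np.ndarray:
    """Per-cell total UMI counts (row sums)."""
    return np.asarray(X.counts.sum(axis=1)).ravel().astype(np.int64)


@dataclasses.dataclass
class NullFit:
    """Maximum-likelihood rank-one null model: mu_cg = depths[c] * fractions[g].

    ``fractions`` sum to one, so ``depths`` are exactly the observed per-cell
    totals and ``mu`` reproduces (row sum * column sum) / grand total.
    """

    depths: np.ndarray
    fractions: np.ndarray
    theta: float
    total: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.theta = _check_theta(self.theta)
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("gene fractions must sum to 1")

    @property
    def is_poisson(self) -> bool:
        return is_poisson(self.theta)

    def mu_column(self, gene: int) -> np.ndarray:
        """Expected counts for one gene across all cells."""
        return self.depths * self.fractions[gene]

    def mu_dense(self) -> np.ndarray:
        """Full dense matrix of expected counts (cells x genes)."""
        return np.outer(self.depths, self.fractions)


def fit_null(X: CountMatrix, theta: float = DEFAULT_THETA) -> NullFit:
    """Fit the rank-one null model in closed form.

    Raises ``ValueError`` on an all-zero matrix; ``theta`` is stored
    unchanged (``POISSON`` marks the Poisson model).
    """
    theta = _check_theta(theta)
    depths = sequencing_depths(X).astype(float)
    total = depths.sum()
    if total == 0:
        raise ValueError("cannot fit the null model to an all-zero count matrix")
    colsums = np.asarray(X.counts.sum(axis=0)).ravel().astype(float)
    fractions = colsums / total
    # force exact normalization against accumulated rounding
    fractions = fractions / fractions.sum()
    return NullFit(depths=depths, fractions=fractions, theta=theta, total=total)


@dataclasses.dataclass
class ResidualMatrix:
    """Dense residual matrix with its provenance.

    ``zero_genes`` flags columns whose total count is zero; their residuals
    are 0 by convention rather than being dropped.
    """

    values: np.ndarray
    kind: str
    theta: float
    clip_bound: float | None
    zero_genes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("pearson", "deviance"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        if self.clip_bound is not None and self.clip_bound < 0:
            raise ValueError("clip bound must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_variance(self) -> np.ndarray:
        """Per-gene (column) population variance of the residuals."""
        return self.values.var(axis=0)


def _resolve_clip(clip, n_cells: int) -> float | None:
    if clip is None:
        return None
    if isinstance(clip, str):
        if clip == "sqrt_n":
            return math.sqrt(n_cells)
        raise ValueError(f"unknown clip specification {clip!r}")
    bound = float(clip)
    if bound < 0:
        raise ValueError("clip bound must be nonnegative")
    return bound


def _pearson_values(x: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    # variance mu + mu^2/theta; zero-expectation entries get residual 0
    var = mu + (0.0 if is_poisson(theta) else mu * mu / theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def _deviance_values(x: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    if is_poisson(theta):
        # x*ln(x/mu) with the x=0 branch explicit via xlogy
        term = xlogy(x, x) - xlogy(x, mu) - (x - mu)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            # log1p form keeps precision when theta dominates x and mu
            term = (
                xlogy(x, x)
                - xlogy(x, mu)
                - (x + theta) * np.log1p((x - mu) / (mu + theta))
            )
        term = np.where((mu == 0) & (x == 0), 0.0, term)
    # roundoff can push exact zeros slightly negative
    term = np.maximum(term, 0.0)
    return np.sign(x - mu) * np.sqrt(2.0 * term)


def pearson_residuals(
    X: CountMatrix,
    theta: float = DEFAULT_THETA,
    clip="sqrt_n",
) -> ResidualMatrix:
    """Analytic Pearson residuals under the rank-one null model.

    ``clip`` is a nonnegative bound, the string ``"sqrt_n"`` (bound at the
    square root of the number of cells — the default), or ``None``.
    """
    fit = fit_null(X, theta)
    bound = _resolve_clip(clip, X.n_cells)
    z = _pearson_values(X.to_dense(), fit.mu_dense(), fit.theta)
    if bound is not None:
        np.clip(z, -bound, bound, out=z)
    return ResidualMatrix(
        values=z,
        kind="pearson",
        theta=fit.theta,
        clip_bound=bound,
        zero_genes=fit.fractions == 0,
    )


def deviance_residuals(X: CountMatrix, theta: float = POISSON) -> ResidualMatrix:
    """Deviance residuals under the rank-one null model.

    For the Poisson model the squared residuals sum to the model deviance;
    the negative-binomial form (finite ``theta``) reduces to the Poisson one
    as ``theta`` grows.
    """
    fit = fit_null(X, theta)
    z = _deviance_values(X.to_dense(), fit.mu_dense(), fit.theta)
    return ResidualMatrix(
        values=z,
        kind="deviance",
        theta=fit.theta,
        clip_bound=None,
        zero_genes=fit.fractions == 0,
    )


def offset_intercepts(X: CountMatrix) -> np.ndarray:
    """Analytic per-gene intercepts of the depth-offset model.

    beta0_g = ln(sum_c X_cg / sum_c n_c); equals ln(mean expression) minus
    ln(mean depth).  Genes with zero total count get ``-inf`` (use
    ``np.isneginf`` to flag them).
    """
    depths = sequencing_depths(X)
    if np.any(depths == 0):
        cell = X.cell_ids[int(np.argmin(depths))]
        raise ValueError(f"cell {cell!r} has zero sequencing depth")
    colsums = np.asarray(X.counts.sum(axis=0)).ravel().astype(float)
    with np.errstate(divide="ignore"):
        return np.log(colsums) - np.log(depths.sum())


def poisson_loglik(X: CountMatrix, depths, fractions) -> float:
    """Rank-one Poisson log-likelihood up to an additive constant.

    sum_cg [ X_cg * ln(n_c p_g) - n_c p_g ].  Requires ``fractions > 0``
    wherever the gene has counts.
    """
    depths = np.asarray(depths, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    rowsums = np.asarray(X.counts.sum(axis=1)).ravel().astype(float)
    colsums = np.asarray(X.counts.sum(axis=0)).ravel().astype(float)
    if np.any((fractions <= 0) & (colsums > 0)):
        raise ValueError("fractions must be positive for genes with counts")
    ll = xlogy(rowsums, depths).sum() + xlogy(colsums, fractions).sum()
    return float(ll - depths.sum() * fractions.sum())


def nb_loglik(X: CountMatrix, depths, fractions, theta: float) -> float:
    """Negative-binomial log-likelihood (fixed theta) up to a constant.

    sum_cg [ X_cg * ln(n_c p_g) - (X_cg + theta) * ln(n_c p_g + theta) ].
    """
    theta = _check_theta(theta)
    if is_poisson(theta):
        raise ValueError("theta must be finite; use poisson_loglik for the limit")
    depths = np.asarray(depths, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    x = X.to_dense()
    mu = np.outer(depths, fractions)
    ll = xlogy(x, mu) - (x + theta) * np.log(mu + theta)
    return float(ll.sum())


def nb_logpmf(x, mu, theta: float) -> np.ndarray:
    """Full negative-binomial log density with mean ``mu`` and shape ``theta``."""
    from scipy.special import gammaln

    theta = _check_theta(theta)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (
        gammaln(x + theta)
        - gammaln(x + 1)
        - gammaln(theta)
        + theta * np.log(theta / (theta + mu))
        + xlogy(x, mu / (theta + mu))
    )


def residual_variance(
    X: CountMatrix,
    kind: str = "pearson",
    theta: float = DEFAULT_THETA,
    clip="sqrt_n",
) -> np.ndarray:
    """Per-gene variance of residuals, computed one gene column at a time.

    Never materializes the dense residual matrix: peak additional memory is
    proportional to one gene column.  Matches the variance of the full
    ``ResidualMatrix`` exactly.
    """
    if kind not in ("pearson", "deviance"):
        raise ValueError(f"unknown residual kind {kind!r}")
    fit = fit_null(X, theta)
    bound = _resolve_clip(clip, X.n_cells)
    Xc = X.counts.tocsc()
    n_cells, n_genes = X.shape
    out = np.empty(n_genes)
    col = np.empty(n_cells)
    for g in range(n_genes):
        col[:] = 0.0
        start, end = Xc.indptr[g], Xc.indptr[g + 1]
        col[Xc.indices[start:end]] = Xc.data[start:end]
        mu = fit.mu_column(g)
        if kind == "pearson":
            z = _pearson_values(col, mu, fit.theta)
        else:
            z = _deviance_values(col, mu, fit.theta)
        if bound is not None:
            np.clip(z, -bound, bound, out=z)
        out[g] = z.var()
    return out
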