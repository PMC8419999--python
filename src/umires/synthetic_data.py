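"""Synthetic UMI datasets: null counts, negative-control grids, and a
labeled multi-type benchmark with an injected rare population.

All generators are pure functions of their spec and seed: identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from umires.count_model import POISSON, CountMatrix, _check_theta, is_poisson


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Specification of a null UMI simulation.

    Depths come from a lognormal around ``mean_depth`` (sigma on the log
    scale) or an explicit list; gene fractions from a power law over gene
    rank, a symmetric Dirichlet, or an explicit list.  ``theta = POISSON``
    selects Poisson noise.
    """

    n_cells: int
    n_genes: int
    theta: float = POISSON
    depth_model: str = "lognormal"
    mean_depth: float = 2000.0
    depth_sigma: float = 0.5
    depths: Sequence[int] | None = None
    fraction_model: str = "power_law"
    power_exponent: float = 1.0
    dirichlet_alpha: float = 1.0
    fractions: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        _check_theta(self.theta)


def _draw_depths(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.depth_model == "empirical":
        if spec.depths is None:
            raise ValueError("empirical depth model requires explicit depths")
        depths = np.asarray(spec.depths, dtype=np.int64)
        if len(depths) != spec.n_cells:
            raise ValueError("explicit depths must have length n_cells")
    elif spec.depth_model == "lognormal":
        mu = math.log(spec.mean_depth) - spec.depth_sigma**2 / 2.0
        depths = np.round(rng.lognormal(mu, spec.depth_sigma, spec.n_cells))
        depths = depths.astype(np.int64)
    else:
        raise ValueError(f"unknown depth model {spec.depth_model!r}")
    depths = np.maximum(depths, 1)
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    return depths


def _draw_fractions(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.fraction_model == "explicit":
        if spec.fractions is None:
            raise ValueError("explicit fraction model requires fractions")
        p = np.asarray(spec.fractions, dtype=float)
        if len(p) != spec.n_genes:
            raise ValueError("explicit fractions must have length n_genes")
    elif spec.fraction_model == "power_law":
        p = np.arange(1, spec.n_genes + 1, dtype=float) ** (-spec.power_exponent)
    elif spec.fraction_model == "dirichlet":
        p = rng.dirichlet(np.full(spec.n_genes, spec.dirichlet_alpha))
    else:
        raise ValueError(f"unknown fraction model {spec.fraction_model!r}")
    if np.any(p < 0):
        raise ValueError("fractions must be nonnegative")
    return p / p.sum()


def _sample_counts(
    mu: np.ndarray, theta: float, rng: np.random.Generator
) -> np.ndarray:
    if is_poisson(theta):
        return rng.poisson(mu)
    return rng.negative_binomial(theta, theta / (theta + mu))


def simulate_null(spec: SimulationSpec) -> CountMatrix:
    """Counts from the rank-one null: X_cg ~ Poisson/NB with mean n_c * p_g.

    Realized row sums differ from the target depths by sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    depths = _draw_depths(spec, rng)
    fractions = _draw_fractions(spec, rng)
    mu = np.outer(depths.astype(float), fractions)
    counts = _sample_counts(mu, spec.theta, rng)
    return CountMatrix.from_dense(counts)


def simulate_negative_control(
    spec: SimulationSpec, theta_grid: Sequence[float]
) -> list[tuple[float, CountMatrix]]:
    """One null dataset per theta, sharing depths and fractions across the grid.

    Emulates negative-control experiments (homogeneous RNA, no biology):
    only the noise model differs between the returned datasets.
    """
    theta_grid = list(theta_grid)
    if not theta_grid:
        raise ValueError("theta grid must be nonempty")
    rng = np.random.default_rng(spec.seed)
    depths = _draw_depths(spec, rng)
    fractions = _draw_fractions(spec, rng)
    mu = np.outer(depths.astype(float), fractions)
    out = []
    for i, theta in enumerate(theta_grid):
        _check_theta(theta)
        sub = np.random.default_rng([spec.seed, i])
        out.append((theta, CountMatrix.from_dense(_sample_counts(mu, theta, sub))))
    return out


@dataclasses.dataclass
class LabeledDataset:
    """A benchmark count matrix with per-cell type labels and ground truth."""

    counts: CountMatrix
    labels: np.ndarray
    truth: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.counts.n_cells:
            raise ValueError("labels must be aligned with cells")


def make_benchmark(
    spec: SimulationSpec,
    n_types: int = 8,
    rare_cells: int = 50,
    n_pseudo_genes: int = 10,
    p_pseudo: float = 1e-3,
    cells_per_type: tuple[int, int] = (400, 600),
    n_marker_genes: int = 30,
    marker_fold: float = 4.0,
    rare_label: str = "rare",
) -> LabeledDataset:
    """Labeled multi-type dataset with an injected rare ninth population.

    Each base type up-regulates a disjoint block of ``n_marker_genes`` genes
    by ``marker_fold`` (a synthetic stand-in for real between-type structure;
    tunable).  The rare type is built by taking ``rare_cells`` cells of the
    first type and appending ``n_pseudo_genes`` pseudo-genes whose counts are
    Poisson(n_i * p_pseudo) in those cells — n_i the cell's realized depth —
    and exactly zero elsewhere.
    """
    if p_pseudo <= 0:
        raise ValueError("p_pseudo must be positive")
    if n_types * n_marker_genes > spec.n_genes:
        raise ValueError("not enough genes for disjoint marker blocks")
    rng = np.random.default_rng(spec.seed)
    sizes = rng.integers(cells_per_type[0], cells_per_type[1] + 1, n_types)
    if rare_cells > sizes[0]:
        raise ValueError("rare_cells exceeds the donor type size")
    n_cells = int(sizes.sum())

    base = _draw_fractions(
        dataclasses.replace(spec, n_cells=n_cells), rng
    )
    # disjoint marker blocks, spread across the expression range
    gene_order = rng.permutation(spec.n_genes)
    type_fractions = np.empty((n_types, spec.n_genes))
    for t in range(n_types):
        block = gene_order[t * n_marker_genes : (t + 1) * n_marker_genes]
        p = base.copy()
        p[block] *= marker_fold
        type_fractions[t] = p / p.sum()

    labels = np.repeat([f"type{t}" for t in range(n_types)], sizes)
    type_index = np.repeat(np.arange(n_types), sizes)
    depth_spec = dataclasses.replace(spec, n_cells=n_cells)
    depths = _draw_depths(depth_spec, rng)
    mu = depths[:, None] * type_fractions[type_index]
    counts = _sample_counts(mu, spec.theta, rng)

    donor = np.flatnonzero(type_index == 0)
    rare_idx = rng.choice(donor, size=rare_cells, replace=False)
    realized = counts.sum(axis=1)
    pseudo = np.zeros((n_cells, n_pseudo_genes), dtype=counts.dtype)
    pseudo[rare_idx] = rng.poisson(
        realized[rare_idx, None] * p_pseudo, (rare_cells, n_pseudo_genes)
    )
    labels = labels.astype(object)
    labels[rare_idx] = rare_label

    full = np.hstack([counts, pseudo])
    gene_ids = [f"gene{j}" for j in range(spec.n_genes)] + [
        f"pseudo{j}" for j in range(n_pseudo_genes)
    ]
    cm = CountMatrix(
        sp.csr_matrix(full), [f"cell{i}" for i in range(n_cells)], gene_ids
    )
    truth = {
        "type_sizes": sizes.tolist(),
        "rare_cells": rare_idx.tolist(),
        "pseudo_gene_ids": gene_ids[spec.n_genes :],
        "p_pseudo": p_pseudo,
        "marker_fold": marker_fold,
        "marker_blocks": {
            f"type{t}": gene_order[t * n_marker_genes : (t + 1) * n_marker_genes].tolist()
            for t in range(n_types)
        },
        "seed": spec.seed,
    }
    return LabeledDataset(counts=cm, labels=labels, truth=truth)
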