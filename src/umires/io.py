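"""Readers and writers for count matrices and result tables.

On disk: Matrix Market coordinate files (1-based, integer field) with
companion ``genes.tsv`` / ``barcodes.tsv``, or dense CSV for toys.
Internally cells are always rows; the 10x genes-as-rows dialect is handled
by the ``orientation`` flag.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from umires.count_model import CountMatrix

ORIENTATIONS = ("cells_rows", "genes_rows")


def _read_id_file(path: pathlib.Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing identifier file: {path}")
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].tolist()


def read_counts(path, orientation: str = "cells_rows") -> CountMatrix:
    """Read a count matrix from ``.mtx`` (with companion TSVs) or CSV.

    For Matrix Market input, ``genes.tsv`` and ``barcodes.tsv`` must sit next
    to the matrix file; ``orientation="genes_rows"`` transposes the 10x
    dialect to cells-as-rows.  Non-integer entries and dimension mismatches
    raise ``ValueError``.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    path = pathlib.Path(path)
    if path.is_dir():
        path = path / "matrix.mtx"
    if path.suffix == ".mtx":
        M = scipy.io.mmread(path)
        data = M.data if sp.issparse(M) else np.asarray(M).ravel()
        if np.any(data != np.floor(data)):
            raise ValueError(f"{path}: matrix contains non-integer entries")
        M = sp.csr_matrix(M)
        genes = _read_id_file(path.parent / "genes.tsv")
        barcodes = _read_id_file(path.parent / "barcodes.tsv")
        if orientation == "genes_rows":
            M = M.T.tocsr()
        if M.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"{path}: matrix shape {M.shape} does not match "
                f"{len(barcodes)} barcodes x {len(genes)} genes"
            )
        return CountMatrix(M, barcodes, genes)
    if path.suffix == ".csv":
        frame = pd.read_csv(path, index_col=0)
        values = frame.to_numpy()
        if not np.all(values == np.floor(values)):
            raise ValueError(f"{path}: matrix contains non-integer entries")
        if orientation == "genes_rows":
            frame = frame.T
        return CountMatrix.from_dense(
            frame.to_numpy(), frame.index.astype(str), frame.columns.astype(str)
        )
    raise ValueError(f"unsupported count file {path}; expected .mtx or .csv")


def write_counts(X: CountMatrix, outdir) -> pathlib.Path:
    """Write matrix.mtx (integer coordinate) + genes.tsv + barcodes.tsv."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", X.counts.tocoo(), field="integer")
    pd.Series(X.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(X.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return outdir


def write_labels(labels, outdir) -> pathlib.Path:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(np.asarray(labels)).to_csv(
        outdir / "labels.tsv", sep="\t", header=False, index=False
    )
    return outdir / "labels.tsv"


def read_labels(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None, dtype=str).iloc[:, 0].to_numpy()


def write_provenance(outdir, command: str, params: dict) -> pathlib.Path:
    """Record inputs, parameters, seed, and version next to the outputs."""
    from umires import __version__

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "params": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in params.items()
        },
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path


def write_matrix(values: np.ndarray, path) -> pathlib.Path:
    """Save a dense matrix as .npy or CSV depending on the suffix."""
    path = pathlib.Path(path)
    if path.suffix == ".npy":
        np.save(path, values)
    elif path.suffix == ".csv":
        pd.DataFrame(values).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported matrix output format: {path.suffix}")
    return path
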