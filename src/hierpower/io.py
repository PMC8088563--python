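"""Reading and writing expression matrices, metadata and simulated datasets.

Dense format: CSV/TSV with genes in rows, first column the gene id, header
row of cell ids. Sparse format: MatrixMarket coordinate triplets (1-based
indices per the standard) with ``genes.tsv`` / ``barcodes.tsv`` sidecars in
the same directory. Metadata: TSV with header
``cell_id<TAB>individual_id[<TAB>phenotype]``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, SimulatedDataset


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_dense(matrix_path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{matrix_path}: missing values are rejected, not imputed")
    return df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns]


def _read_mtx(matrix_path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    d = matrix_path.parent
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} barcodes)"
        )
    return mat, genes, cells


def read_metadata(metadata_path) -> pd.DataFrame:
    """Read the cell metadata table (cell_id, individual_id[, phenotype])."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={0: str, 1: str})
    required = {"cell_id", "individual_id"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}; got {list(meta.columns)}")
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids in metadata: {dups[:10]}")
    return meta


def read_expression(matrix_path, metadata_path, format: str = "dense") -> ExpressionMatrix:
    """Read an expression matrix plus its cell -> individual mapping.

    Cells are returned in metadata order. Any mismatch between the matrix
    cell set and the metadata cell set is an error naming the offenders.
    """
    matrix_path = Path(matrix_path)
    if format == "dense":
        values, gene_ids, cell_ids = _read_dense(matrix_path)
    elif format == "mtx":
        values, gene_ids, cell_ids = _read_mtx(matrix_path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'dense' or 'mtx'")

    meta = read_metadata(metadata_path)
    matrix_cells = set(cell_ids)
    meta_cells = set(meta["cell_id"])
    missing_from_meta = sorted(matrix_cells - meta_cells)
    missing_from_matrix = sorted(meta_cells - matrix_cells)
    if missing_from_meta or missing_from_matrix:
        raise ValueError(
            "metadata/matrix cell mismatch; "
            f"in matrix but not metadata: {missing_from_meta[:10]}; "
            f"in metadata but not matrix: {missing_from_matrix[:10]}"
        )
    order = [cell_ids.index(c) for c in meta["cell_id"]]
    return ExpressionMatrix(
        values=values[:, order],
        gene_ids=gene_ids,
        cell_ids=meta["cell_id"].tolist(),
        individual_of_cell=meta["individual_id"].to_numpy(dtype=object),
    )


def _write_dense(values: np.ndarray, gene_ids, cell_ids, path: Path) -> None:
    df = pd.DataFrame(values, index=gene_ids, columns=cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep_for(path))


def _write_mtx(values: np.ndarray, gene_ids, cell_ids, path: Path) -> None:
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(values))
    d = path.parent
    pd.Series(gene_ids).to_csv(d / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(cell_ids).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)


def write_simulated(dataset: SimulatedDataset, out_prefix, format: str = "dense") -> dict[str, str]:
    """Write a simulated dataset as counts + cell metadata + gene truth table.

    Returns the paths written. The counts/metadata pair round-trips through
    :func:`read_expression`.
    """
    out_prefix = str(out_prefix)
    parent = Path(out_prefix).parent
    os.makedirs(parent, exist_ok=True)

    if format == "dense":
        counts_path = Path(out_prefix + "_counts.tsv")
        _write_dense(dataset.counts, dataset.gene_ids, dataset.cell_ids, counts_path)
    elif format == "mtx":
        counts_path = Path(out_prefix + "_counts.mtx")
        _write_mtx(dataset.counts, dataset.gene_ids, dataset.cell_ids, counts_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    pheno = dict(zip(dataset.individual_ids, dataset.phenotype_of_individual))
    cells = pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "individual_id": dataset.individual_of_cell,
            "phenotype": [pheno[i] for i in dataset.individual_of_cell],
        }
    )
    if dataset.kind == "binary":
        cells["phenotype"] = cells["phenotype"].astype(int)
    cells_path = parent / (Path(out_prefix).name + "_cells.tsv")
    cells.to_csv(cells_path, sep="\t", index=False)

    truth = pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "is_de": dataset.de_flags.astype(int),
            "applied_effect": dataset.applied_effect,
        }
    )
    truth_path = parent / (Path(out_prefix).name + "_genes.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    return {"counts": str(counts_path), "cells": str(cells_path), "genes": str(truth_path)}


def write_expression(x: ExpressionMatrix, matrix_path, metadata_path, format: str = "dense") -> None:
    """Write a bare matrix + metadata pair readable by :func:`read_expression`."""
    matrix_path = Path(matrix_path)
    os.makedirs(matrix_path.parent, exist_ok=True)
    if format == "dense":
        _write_dense(x.values, x.gene_ids, x.cell_ids, matrix_path)
    elif format == "mtx":
        _write_mtx(x.values, x.gene_ids, x.cell_ids, matrix_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    pd.DataFrame({"cell_id": x.cell_ids, "individual_id": x.individual_of_cell}).to_csv(
        metadata_path, sep="\t", index=False
    )
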