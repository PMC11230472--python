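"""Readers and writers for the on-disk formats the tool touches.

Supported inputs are the CellRanger MTX triplet (matrix.mtx + genes.tsv +
barcodes.tsv, genes x cells on disk) and dense delimited tables with a gene
header row and a cell-id first column.  Labels travel in a two-column
``cell_id,label`` file and are matched by identifier, never by row order.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import CellMatrix, LabeledDataset

__all__ = [
    "read_mtx_triplet",
    "read_dense",
    "read_labels",
    "intersect_genes",
    "write_labels",
    "write_mtx_triplet",
    "write_dense",
]


class FormatError(ValueError):
    """A file parsed but does not satisfy the expected layout."""


def _read_side_file(path) -> list[str]:
    """First whitespace/tab-delimited column of a one-entry-per-line file."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0].split(",")[0])
    return out


def read_mtx_triplet(matrix_path, genes_path, barcodes_path) -> CellMatrix:
    """Read a CellRanger-style MTX triplet into a cells x genes CellMatrix.

    The on-disk matrix is genes x cells; it is transposed on read.  The gene
    file may have one or two columns (CellRanger v2 writes Ensembl id and
    symbol); the first column is used as the gene identifier.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as exc:  # malformed or empty MatrixMarket file
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_side_file(genes_path)
    barcodes = _read_side_file(barcodes_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"{matrix_path} has {n_genes} rows but {genes_path} lists "
            f"{len(genes)} genes"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"{matrix_path} has {n_cells} columns but {barcodes_path} lists "
            f"{len(barcodes)} barcodes"
        )
    if len(set(barcodes)) != len(barcodes):
        seen: set[str] = set()
        dups = sorted({b for b in barcodes if b in seen or seen.add(b)})
        raise FormatError(f"duplicate barcodes in {barcodes_path}: {dups[:10]}")
    dense = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
    ).T
    return CellMatrix(dense, np.array(barcodes, dtype=object),
                      np.array(genes, dtype=object), layer="counts")


def write_mtx_triplet(m: CellMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write a CellMatrix as a genes x cells MTX triplet (inverse of read)."""
    scipy.io.mmwrite(os.fspath(matrix_path), scipy.sparse.coo_matrix(m.values.T))
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in m.cell_ids))


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_dense(path, labels_path=None, layer: str = "counts"):
    """Read a dense cells x genes table; optionally attach labels.

    The table must carry gene names in the header and cell ids in the first
    column.  When ``labels_path`` is given every matrix cell must be
    labeled, and every labeled cell must exist in the matrix; the result is
    a :class:`LabeledDataset`, otherwise a :class:`CellMatrix`.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    m = CellMatrix(
        df.to_numpy(dtype=float),
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
        layer=layer,
    )
    if labels_path is None:
        return m
    label_map = read_labels(labels_path)
    missing = [c for c in label_map if c not in set(m.cell_ids.tolist())]
    if missing:
        raise FormatError(
            f"labels file {labels_path} names cells absent from the matrix: "
            f"{missing[:10]}"
        )
    unlabeled = [c for c in m.cell_ids.tolist() if c not in label_map]
    if unlabeled:
        raise FormatError(
            f"reference cells without a label in {labels_path}: {unlabeled[:10]}"
        )
    labels = np.array([label_map[c] for c in m.cell_ids.tolist()], dtype=object)
    return LabeledDataset(m, labels)


def read_labels(path) -> dict[str, str]:
    """Read a two-column cell_id,label file into an id -> label mapping."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = [c.strip() for c in df.columns]
    if len(cols) < 2:
        raise FormatError(f"{path}: expected columns cell_id,label")
    df.columns = cols
    id_col = "cell_id" if "cell_id" in cols else cols[0]
    label_col = "label" if "label" in cols else cols[1]
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate cell ids in labels file")
    return dict(zip(ids, df[label_col].astype(str).tolist()))


def intersect_genes(a: CellMatrix, b: CellMatrix) -> tuple[CellMatrix, CellMatrix]:
    """Restrict both matrices to their shared genes, in a common order.

    Gene matching is by exact string identity.  The shared genes keep the
    order they have in ``a`` so the operation is deterministic; cells are
    untouched.
    """
    b_set = set(b.gene_ids.tolist())
    shared = [g for g in a.gene_ids.tolist() if g in b_set]
    if not shared:
        raise ValueError("gene sets are disjoint: no shared genes to intersect")
    return a.subset_genes(shared), b.subset_genes(shared)


def write_labels(cell_ids, labels, path) -> None:
    """Write cell labels as a two-column CSV with header ``cell_id,label``."""
    cell_ids = list(cell_ids)
    labels = list(labels)
    if len(cell_ids) != len(labels):
        raise ValueError(
            f"{len(cell_ids)} cell ids but {len(labels)} labels"
        )
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(path, index=False)


def write_dense(m: CellMatrix, path) -> None:
    """Write a CellMatrix as a dense delimited table (inverse of read_dense)."""
    pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids).to_csv(
        path, sep=_sep_for(path)
    )
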