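"""Core in-memory containers shared by every stage of the pipeline.

All expression data is held as a dense ``cells x genes`` float array.  The
10X on-disk orientation (genes x cells) is transposed at the I/O boundary,
so downstream code never has to think about orientation again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellMatrix",
    "LabeledDataset",
    "ProbabilityMatrix",
    "Composition",
    "EntropyVector",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids.tolist())):
        seen: set[str] = set()
        dups = sorted({i for i in ids.tolist() if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CellMatrix:
    """Expression values for a set of cells over a common gene universe.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` array.  Raw counts when ``layer == "counts"``
        (finite, non-negative), log-normalized expression when
        ``layer == "lognorm"``.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns respectively.
    layer
        Either ``"counts"`` or ``"lognorm"``.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        n, g = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if g != len(self.gene_ids):
            raise ValueError(
                f"matrix has {g} columns but {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if self.layer not in ("counts", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.layer == "counts" and np.any(self.values < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "CellMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids.tolist())}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return CellMatrix(
            self.values[:, idx],
            self.cell_ids.copy(),
            np.asarray(list(gene_ids), dtype=object),
            layer=self.layer,
        )

    def subset_cells(self, row_idx: np.ndarray) -> "CellMatrix":
        """Row subset by positional index (may repeat rows)."""
        idx = np.asarray(row_idx, dtype=int)
        return CellMatrix(
            self.values[idx],
            self.cell_ids[idx],
            self.gene_ids.copy(),
            layer=self.layer,
        )


@dataclass
class LabeledDataset:
    """A :class:`CellMatrix` with one cell-type label per cell.

    ``origin`` optionally records provenance per cell (e.g. ``"reference"``
    vs ``"target"``) for expanded reference pools.
    """

    matrix: CellMatrix
    labels: np.ndarray
    type_names: list[str] = field(default_factory=list)
    origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.matrix.n_cells:
            raise ValueError(
                f"{len(self.labels)} labels for {self.matrix.n_cells} cells"
            )
        if not self.type_names:
            self.type_names = sorted(set(self.labels.tolist()))
        present = set(self.labels.tolist())
        unknown = present - set(self.type_names)
        if unknown:
            raise ValueError(f"labels not in type_names: {sorted(unknown)}")
        absent = [t for t in self.type_names if t not in present]
        if absent:
            raise ValueError(f"type_names never used in labels: {absent}")
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=object)
            if len(self.origin) != self.matrix.n_cells:
                raise ValueError("origin length must match cell count")

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def composition(self) -> "Composition":
        """Empirical cell-type proportions of this dataset (kind 'reference')."""
        counts = np.array(
            [np.sum(self.labels == t) for t in self.type_names], dtype=float
        )
        return Composition(counts / counts.sum(), list(self.type_names), "reference")


@dataclass
class ProbabilityMatrix:
    """Row-stochastic per-cell class-membership probabilities."""

    probs: np.ndarray
    cell_ids: np.ndarray
    type_names: list[str]

    _ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.type_names = list(self.type_names)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.type_names):
            raise ValueError("probs must be n x K with K == len(type_names)")
        if self.probs.shape[0] != len(self.cell_ids):
            raise ValueError("one row per cell id required")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        rowsum = self.probs.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > self._ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(
                f"row {bad} sums to {rowsum[bad]!r}, not 1 within 1e-6"
            )

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.type_names)


#: allowed Composition tags: the reference's own proportions (P^R), the
#: target's true proportions (P^T), the round-1 estimate (P-hat^T) and the
#: uniform equal-weight vector (P-bar).
COMPOSITION_KINDS = ("reference", "oracle_target", "estimated_target", "equal")


@dataclass
class Composition:
    """A probability vector over cell types."""

    proportions: np.ndarray
    type_names: list[str]
    kind: str = "reference"

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.type_names = list(self.type_names)
        if self.proportions.ndim != 1 or len(self.proportions) != len(self.type_names):
            raise ValueError("one proportion per type name required")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(self.proportions.sum() - 1.0) > self._SUM_TOL:
            raise ValueError(
                f"proportions sum to {self.proportions.sum()!r}, not 1 within 1e-9"
            )
        if self.kind not in COMPOSITION_KINDS:
            raise ValueError(f"unknown composition kind {self.kind!r}")

    @classmethod
    def equal(cls, type_names) -> "Composition":
        k = len(type_names)
        return cls(np.full(k, 1.0 / k), list(type_names), "equal")

    def as_dict(self) -> dict[str, float]:
        return {t: float(p) for t, p in zip(self.type_names, self.proportions)}


@dataclass
class EntropyVector:
    """Shannon entropy (nats) of each cell's predicted probability row."""

    values: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.values) != len(self.cell_ids):
            raise ValueError("one entropy per cell id required")
        if np.any(self.values < -1e-12):
            raise ValueError("entropies must be non-negative")
        self.values = np.maximum(self.values, 0.0)
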