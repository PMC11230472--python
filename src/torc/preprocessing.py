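"""Count normalization and F-test gene selection.

Normalization is the standard counts-per-cell scaling followed by a
natural-log ``log1p``.  Feature selection ranks genes by the one-way
fixed-effects ANOVA F statistic across cell-type groups, computed on the
labeled reference only so no target information leaks into the gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CellMatrix, LabeledDataset

__all__ = ["normalize_log", "f_test_select", "FeatureSelection"]

#: floor for the within-group mean square so that perfect discriminators
#: (zero within-group variance, positive between-group variance) receive a
#: very large finite statistic and rank first.
_WITHIN_MS_FLOOR = 1e-12


@dataclass
class FeatureSelection:
    """Result of F-test gene selection.

    ``selected_gene_ids`` are ordered by descending F statistic (ties broken
    by ascending gene id); ``f_statistics`` covers every candidate gene in
    the input's gene order.
    """

    selected_gene_ids: list[str]
    f_statistics: np.ndarray
    n_features: int

    def __post_init__(self) -> None:
        self.f_statistics = np.asarray(self.f_statistics, dtype=float)
        if len(self.selected_gene_ids) != self.n_features:
            raise ValueError("selected_gene_ids length must equal n_features")
        if np.any(~np.isfinite(self.f_statistics)) or np.any(self.f_statistics < 0):
            raise ValueError("F statistics must be finite and non-negative")


def normalize_log(m: CellMatrix, scale: float = 10_000.0) -> CellMatrix:
    """Scale each cell to ``scale`` total counts, then apply log1p.

    Cells with zero total count cannot be scaled and are rejected with an
    error listing their identifiers.
    """
    if m.layer != "counts":
        raise ValueError(f"normalize_log expects counts, got layer {m.layer!r}")
    totals = m.values.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = m.cell_ids[zero].tolist()
        raise ValueError(f"cells with zero total count cannot be normalized: {ids[:10]}")
    out = np.log1p(m.values * (scale / totals[:, None]))
    return CellMatrix(out, m.cell_ids.copy(), m.gene_ids.copy(), layer="lognorm")


def f_statistics(values: np.ndarray, labels: np.ndarray, type_names) -> np.ndarray:
    """Per-gene one-way ANOVA F statistic across label groups.

    Vectorized two-pass computation: between-group mean square over within-
    group mean square with K-1 and n-K degrees of freedom.  Genes that are
    constant everywhere get 0; genes with zero within-group variance but
    real group differences get a huge finite value via the floored
    denominator.
    """
    n, _ = values.shape
    groups = [np.where(labels == t)[0] for t in type_names]
    k = len(groups)
    if k < 2:
        raise ValueError("F test requires at least 2 cell types")
    for t, idx in zip(type_names, groups):
        if idx.size < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for idx in groups:
        sub = values[idx]
        gm = sub.mean(axis=0)
        ss_between += idx.size * (gm - grand) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    f = ms_between / np.maximum(ms_within, _WITHIN_MS_FLOOR)
    # genes with no between-group signal (including all-constant genes,
    # where both mean squares vanish) are uninformative
    f[ms_between == 0.0] = 0.0
    return f


def f_test_select(ref: LabeledDataset, n_features: int) -> FeatureSelection:
    """Select the ``n_features`` genes with the largest F statistics.

    Requires log-normalized data, at least two types and two cells per type.
    The returned gene order is total: descending F, ties broken by ascending
    gene id, so selection is deterministic.
    """
    m = ref.matrix
    if m.layer != "lognorm":
        raise ValueError(f"f_test_select expects lognorm data, got {m.layer!r}")
    if n_features > m.n_genes:
        raise ValueError(
            f"n_features={n_features} exceeds the {m.n_genes} candidate genes"
        )
    f = f_statistics(m.values, ref.labels, ref.type_names)
    order = sorted(range(m.n_genes), key=lambda i: (-f[i], m.gene_ids[i]))
    selected = [str(m.gene_ids[i]) for i in order[:n_features]]
    return FeatureSelection(selected, f, n_features)
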