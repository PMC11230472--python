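"""Synthetic reference/target generator with known ground truth.

Counts are negative binomial with gene-and-type-specific means: every gene
has a shared baseline mean, each type adds ``marker_logfc`` (natural-log
scale) to the log-mean of its own marker genes, and designated confusable
type pairs have their distinguishing marker effects shrunk toward the pair
average.  The target can additionally receive a per-gene multiplicative
log-normal batch factor, emulating domain shift between studies without
touching composition.  Cell-type counts come from largest-remainder
apportionment, so the requested compositions are hit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import apportion
from .types import CellMatrix, Composition, LabeledDataset

__all__ = ["SimSpec", "simulate_pair", "reversal_scenario"]


@dataclass(frozen=True)
class SimSpec:
    """Generative parameters for one reference/target pair.

    ``separation_scale`` in a confusable pair entry is the fraction of the
    pair's distinguishing marker contrast that is retained: 1 keeps the
    full contrast, 0 collapses the two profiles into one so the pair is
    indistinguishable.  ``batch_effect_sd`` is the
    standard deviation of the per-gene log-normal factor applied to target
    means only.
    """

    K: int = 4
    n_genes: int = 500
    n_marker_genes_per_type: int = 25
    marker_logfc: float = 0.9
    confusable_pairs: tuple[tuple[int, int, float], ...] = ()
    ref_composition: tuple[float, ...] | None = None
    target_composition: tuple[float, ...] | None = None
    n_ref: int = 2000
    n_target: int = 2000
    batch_effect_sd: float = 0.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_marker_genes_per_type * self.K > self.n_genes:
            raise ValueError(
                f"{self.K} types x {self.n_marker_genes_per_type} markers "
                f"exceed {self.n_genes} genes"
            )
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        for a, b, s in self.confusable_pairs:
            if not (0 <= a < self.K and 0 <= b < self.K and a != b):
                raise ValueError(f"confusable pair ({a}, {b}) out of range")
            if not (0.0 <= s <= 1.0):
                raise ValueError("separation_scale must lie in [0, 1]")

    @property
    def type_names(self) -> list[str]:
        return [f"type{k}" for k in range(self.K)]

    def composition(self, which: str) -> Composition:
        props = self.ref_composition if which == "ref" else self.target_composition
        if props is None:
            props = tuple(1.0 / self.K for _ in range(self.K))
        kind = "reference" if which == "ref" else "oracle_target"
        return Composition(np.asarray(props, dtype=float), self.type_names, kind)


def _log_mean_profiles(spec: SimSpec) -> np.ndarray:
    """(K, n_genes) natural-log mean matrix, confusable pairs mixed."""
    log_mu = np.full((spec.K, spec.n_genes), np.log(spec.baseline_mean))
    for k in range(spec.K):
        start = k * spec.n_marker_genes_per_type
        log_mu[k, start:start + spec.n_marker_genes_per_type] += spec.marker_logfc
    for a, b, s in spec.confusable_pairs:
        # the pair shares (1 - s) of its marker effects: each profile keeps
        # fraction s of its distinguishing contrast (s=0 collapses the pair)
        pair_mean = 0.5 * (log_mu[a] + log_mu[b])
        log_mu[a] = s * log_mu[a] + (1.0 - s) * pair_mean
        log_mu[b] = s * log_mu[b] + (1.0 - s) * pair_mean
    return log_mu


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Negative binomial draws, mean mu, variance mu + mu^2/dispersion."""
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p).astype(float)


def _labels_for(comp: Composition, n: int, rng: np.random.Generator,
                shuffle: bool = True) -> np.ndarray:
    counts = apportion(comp, n)
    labels = np.repeat(np.asarray(comp.type_names, dtype=object), counts)
    if shuffle:
        rng.shuffle(labels)
    return labels


def simulate_pair(spec: SimSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Generate a (reference, target) pair with known labels.

    The two datasets share one set of type profiles; they differ only in
    composition and, when ``batch_effect_sd > 0``, in a per-gene
    multiplicative batch factor on target means.  Reproducible from
    ``spec.seed``; the batch effect consumes its own random stream, so
    changing ``batch_effect_sd`` changes target values but not labels.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_ref, ss_target, ss_batch = root.spawn(3)
    log_mu = _log_mean_profiles(spec)
    gene_ids = np.array([f"gene{g}" for g in range(spec.n_genes)], dtype=object)
    type_index = {t: k for k, t in enumerate(spec.type_names)}

    def build(which: str, n: int, ss, batch: np.ndarray | None) -> LabeledDataset:
        rng = np.random.default_rng(ss)
        labels = _labels_for(spec.composition(which), n, rng)
        mu = np.exp(log_mu)[[type_index[t] for t in labels]]
        if batch is not None:
            mu = mu * batch[None, :]
        counts = _draw_counts(rng, mu, spec.dispersion)
        ids = np.array([f"{which}_cell{i}" for i in range(n)], dtype=object)
        matrix = CellMatrix(counts, ids, gene_ids.copy(), layer="counts")
        present = sorted(set(labels.tolist()))
        return LabeledDataset(matrix, labels, present)

    batch = None
    if spec.batch_effect_sd > 0:
        batch_rng = np.random.default_rng(ss_batch)
        batch = np.exp(batch_rng.normal(0.0, spec.batch_effect_sd, spec.n_genes))
    ref = build("ref", spec.n_ref, ss_ref, None)
    target = build("target", spec.n_target, ss_target, batch)
    return ref, target


def reversal_scenario(base: SimSpec, pair: tuple[int, int],
                      odds_ref: float, odds_target: float) -> SimSpec:
    """Set a type pair's odds in reference vs target, conserving all else.

    With pair mass ``m`` and odds ``r``, the pair's proportions become
    ``(m r/(1+r), m/(1+r))``.  The pair's combined mass and every other
    type's proportion are unchanged, so e.g. odds 4 in the reference and
    1/4 in the target reverse the pair between the two datasets.
    """
    a, b = pair
    if not (0 <= a < base.K and 0 <= b < base.K and a != b):
        raise ValueError(f"pair ({a}, {b}) out of range")
    if odds_ref <= 0 or odds_target <= 0:
        raise ValueError("odds must be positive")

    def adjust(props, odds: float) -> tuple[float, ...]:
        props = np.asarray(
            props if props is not None else [1.0 / base.K] * base.K, dtype=float
        )
        mass = props[a] + props[b]
        if mass == 0:
            raise ValueError(f"pair ({a}, {b}) has zero combined mass")
        out = props.copy()
        out[a] = mass * odds / (1.0 + odds)
        out[b] = mass / (1.0 + odds)
        return tuple(out.tolist())

    return replace(
        base,
        ref_composition=adjust(base.ref_composition, odds_ref),
        target_composition=adjust(base.target_composition, odds_target),
    )
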