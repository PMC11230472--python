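"""Target-oriented reference construction (TORC).

The quality of a supervised cell-typer depends on how well its reference
matches the target, in two distinct ways: the cell-type composition (class
priors) and the cell-type-specific expression profiles (domain shift).
TORC addresses both with a two-round strategy:

1. Train a classifier on the original reference and predict the target.
2. From the predicted probability matrix, estimate the target composition
   ``P-hat^T`` and score each cell's prediction entropy.
3. Optionally add low-entropy (high-confidence) target cells, carrying
   their round-1 pseudo-labels, to an expanded reference pool — this pulls
   target-domain expression into the training data.
4. Resample the pool to match ``P-hat^T`` (largest-remainder apportionment,
   without replacement where the pool suffices) and retrain on the
   constructed reference to produce the final labels.

Exactly two rounds are run; pseudo-labels assigned in round 1 are never
revisited.  All randomness flows from a single root seed through an
explicit child-seed derivation, so a full run is reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classifier as clf_mod
from .classifier import ClassifierSpec, FittedClassifier, predict_labels
from .preprocessing import f_test_select, normalize_log
from .io import intersect_genes
from .types import (
    CellMatrix,
    Composition,
    EntropyVector,
    LabeledDataset,
    ProbabilityMatrix,
)

__all__ = [
    "TorcConfig",
    "TorcResult",
    "entropy",
    "estimate_composition",
    "select_confident",
    "expand_pool",
    "apportion",
    "resample_reference",
    "construct_reference_oracle",
    "run_torc",
]

logger = logging.getLogger("torc")

TARGET_PREFIX = "target:"


@dataclass(frozen=True)
class TorcConfig:
    """Knobs of the two-round procedure.

    ``entropy_quantile`` is the per-type (or global) fraction of lowest-
    entropy cells admitted into the expanded pool.  ``reference_size``
    controls the constructed reference's cell count; ``"match_original"``
    keeps the input reference's size so only composition and provenance
    change between rounds.
    """

    expand_pool: bool = True
    entropy_quantile: float = 0.10
    per_type_gating: bool = True
    composition_mode: str = "hard"
    reference_size: int | str = "match_original"
    sample_with_replacement_fallback: bool = True
    min_cells_per_type: int = 10
    normalize_scale: float = 10_000.0
    n_features: int = 1000
    reselect_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.entropy_quantile <= 1.0):
            raise ValueError("entropy_quantile must lie in (0, 1]")
        if self.composition_mode not in ("hard", "soft"):
            raise ValueError("composition_mode must be 'hard' or 'soft'")
        if isinstance(self.reference_size, str):
            if self.reference_size != "match_original":
                raise ValueError(
                    "reference_size must be a positive integer or 'match_original'"
                )
        elif self.reference_size <= 0:
            raise ValueError("reference_size must be positive")
        if self.min_cells_per_type < 0:
            raise ValueError("min_cells_per_type must be >= 0")


@dataclass
class TorcResult:
    """Everything a run produces, sufficient to audit each stage."""

    final_labels: np.ndarray
    first_round_labels: np.ndarray
    cell_ids: np.ndarray
    estimated_composition: Composition
    entropies: EntropyVector
    pool_added_cell_ids: list[str]
    constructed_reference_composition: Composition
    seed: int
    child_seeds: dict[str, int] = field(default_factory=dict)


def entropy(p: ProbabilityMatrix) -> EntropyVector:
    """Shannon entropy of each probability row, in nats.

    ``H_i = -sum_k p_ik ln p_ik`` with the convention ``0 ln 0 = 0``; the
    result lies in ``[0, ln K]`` and is 0 exactly for one-hot rows.
    """
    pr = p.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pr > 0.0, pr * np.log(pr), 0.0)
    return EntropyVector(-terms.sum(axis=1), p.cell_ids.copy())


def estimate_composition(p: ProbabilityMatrix, mode: str = "hard") -> Composition:
    """Estimate the target's cell-type composition from round-1 output.

    ``"hard"`` counts argmax labels (the plain reading of predicting the
    target's composition); ``"soft"`` averages the probability columns,
    shrinking the estimate toward the classifier's uncertainty.  Both agree
    when rows are one-hot.
    """
    if mode == "hard":
        idx = np.argmax(p.probs, axis=1)
        counts = np.bincount(idx, minlength=p.n_types).astype(float)
        props = counts / p.n_cells
    elif mode == "soft":
        props = p.probs.mean(axis=0)
        props = props / props.sum()
    else:
        raise ValueError(f"unknown composition mode {mode!r}")
    return Composition(props, list(p.type_names), "estimated_target")


def _lower_quantile(values: np.ndarray, q: float) -> float:
    """Inclusive lower empirical quantile (type 1, inverted CDF)."""
    return float(np.quantile(values, q, method="inverted_cdf"))


def select_confident(e: EntropyVector, labels: np.ndarray,
                     cfg: TorcConfig) -> list[str]:
    """Identifiers of high-confidence (low-entropy) target cells.

    With per-type gating (default) the entropy cutoff is the
    ``entropy_quantile``-th quantile within each predicted type, so easy,
    abundant types cannot crowd rare types out of the pool; otherwise one
    global quantile is used.  Comparison is inclusive (<=), so ties at the
    cutoff are kept.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(e.values):
        raise ValueError("entropies and labels must be aligned by cell")
    keep = np.zeros(len(labels), dtype=bool)
    if cfg.per_type_gating:
        for t in sorted(set(labels.tolist())):
            mask = labels == t
            cut = _lower_quantile(e.values[mask], cfg.entropy_quantile)
            keep |= mask & (e.values <= cut)
    else:
        cut = _lower_quantile(e.values, cfg.entropy_quantile)
        keep = e.values <= cut
    return [str(c) for c in e.cell_ids[keep]]


def expand_pool(ref: LabeledDataset, target: CellMatrix,
                confident_ids: list[str], first_labels: np.ndarray) -> LabeledDataset:
    """Append confidently predicted target cells to the reference pool.

    Added cells carry their round-1 pseudo-labels and a ``target:`` id
    prefix plus an origin flag, so provenance survives resampling.  With no
    confident cells the pool is the reference itself.
    """
    if not confident_ids:
        return ref
    id_to_row = {str(c): i for i, c in enumerate(target.cell_ids)}
    missing = [c for c in confident_ids if c not in id_to_row]
    if missing:
        raise ValueError(f"confident ids not in target: {missing[:10]}")
    rows = np.array([id_to_row[c] for c in confident_ids], dtype=int)
    label_by_id = dict(zip([str(c) for c in target.cell_ids], first_labels))
    added_labels = np.array([label_by_id[c] for c in confident_ids], dtype=object)

    new_ids = np.array([TARGET_PREFIX + c for c in confident_ids], dtype=object)
    collisions = sorted(set(new_ids.tolist()) & set(ref.matrix.cell_ids.tolist()))
    if collisions:
        raise ValueError(f"cell id collision after prefixing: {collisions[:10]}")
    if ref.matrix.layer != target.layer:
        raise ValueError("reference and target must be in the same layer")

    values = np.vstack([ref.matrix.values, target.values[rows]])
    cell_ids = np.concatenate([ref.matrix.cell_ids, new_ids])
    matrix = CellMatrix(values, cell_ids, ref.matrix.gene_ids.copy(),
                        layer=ref.matrix.layer)
    labels = np.concatenate([ref.labels, added_labels])
    origin = np.concatenate([
        np.full(ref.n_cells, "reference", dtype=object),
        np.full(len(rows), "target", dtype=object),
    ])
    return LabeledDataset(matrix, labels, list(ref.type_names), origin=origin)


def apportion(comp: Composition, size: int, min_cells_per_type: int = 0) -> np.ndarray:
    """Largest-remainder (Hamilton) integer apportionment of ``size`` cells.

    Exact-sum integer counts per type: floor of ``size * p`` plus one for
    the largest fractional remainders, ties broken by type order.  Types
    with zero proportion get zero.  A ``min_cells_per_type`` floor is then
    applied to types with positive proportion, funded by repeatedly
    decrementing the currently most abundant type.
    """
    props = comp.proportions
    nonzero = props > 0.0
    k_nonzero = int(nonzero.sum())
    if size < k_nonzero * max(min_cells_per_type, 1):
        raise ValueError(
            f"size {size} cannot give each of {k_nonzero} nonzero types "
            f"at least {max(min_cells_per_type, 1)} cells"
        )
    raw = props * size
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    shortfall = size - int(counts.sum())
    # ties broken by type order: stable sort on descending remainder
    order = np.argsort(-remainder, kind="stable")
    for i in order[:shortfall]:
        counts[i] += 1
    counts[~nonzero] = 0
    # re-add any mass floor() sent to zero-proportion types
    deficit = size - int(counts.sum())
    if deficit:
        order = np.argsort(-remainder, kind="stable")
        for i in order:
            if deficit == 0:
                break
            if nonzero[i]:
                counts[i] += 1
                deficit -= 1
    if min_cells_per_type > 0:
        floor = min_cells_per_type
        for i in np.where(nonzero & (counts < floor))[0]:
            need = floor - counts[i]
            counts[i] = floor
            for _ in range(need):
                donors = np.where(nonzero & (counts > floor))[0]
                j = donors[np.argmax(counts[donors])]
                counts[j] -= 1
    assert counts.sum() == size
    return counts


def resample_reference(pool: LabeledDataset, comp: Composition, size: int,
                       cfg: TorcConfig, rng_seed: int) -> LabeledDataset:
    """Draw a constructed reference matching ``comp`` from the pool.

    Per-type counts come from :func:`apportion`, so the sample composition
    deviates from ``comp`` by less than one cell per type (before the
    ``min_cells_per_type`` floor).  Sampling is without replacement when a
    type's pool suffices; otherwise cells are duplicated (if the fallback
    is enabled) or the type is capped at its pool count with a warning.
    """
    if comp.type_names != list(pool.type_names):
        # align composition onto pool type order; unknown types are an error
        unknown = set(comp.type_names) - set(pool.type_names)
        missing_mass = [t for t in unknown
                        if comp.proportions[comp.type_names.index(t)] > 0]
        if missing_mass:
            raise ValueError(
                f"composition gives positive mass to types absent from the "
                f"pool: {sorted(missing_mass)}"
            )
        props = np.array([
            comp.proportions[comp.type_names.index(t)] if t in comp.type_names
            else 0.0 for t in pool.type_names
        ])
        comp = Composition(props / props.sum(), list(pool.type_names), comp.kind)
    counts = apportion(comp, size, cfg.min_cells_per_type)
    rng = np.random.default_rng(rng_seed)
    rows: list[np.ndarray] = []
    for t, want in zip(pool.type_names, counts):
        if want == 0:
            continue
        avail = np.where(pool.labels == t)[0]
        if avail.size == 0:
            raise ValueError(
                f"composition requires type {t!r} but the pool has no such cells"
            )
        if want <= avail.size:
            rows.append(rng.choice(avail, size=want, replace=False))
        elif cfg.sample_with_replacement_fallback:
            rows.append(rng.choice(avail, size=want, replace=True))
        else:
            logger.warning(
                "type %s: wanted %d cells but pool has %d; capping", t, want,
                avail.size,
            )
            rows.append(avail.copy())
    idx = np.concatenate(rows)
    # cells drawn twice under the with-replacement fallback get fresh ids
    seen: dict[str, int] = {}
    out_ids = []
    for c in pool.matrix.cell_ids[idx].astype(str).tolist():
        n = seen.get(c, 0)
        out_ids.append(c if n == 0 else f"{c}#dup{n}")
        seen[c] = n + 1
    matrix = CellMatrix(pool.matrix.values[idx],
                        np.array(out_ids, dtype=object),
                        pool.matrix.gene_ids.copy(), layer=pool.matrix.layer)
    labels = pool.labels[idx]
    origin = pool.origin[idx] if pool.origin is not None else None
    present = sorted(set(labels.tolist()))
    return LabeledDataset(matrix, labels, present, origin=origin)


def construct_reference_oracle(ref_pool: LabeledDataset, comp: Composition,
                               size: int, seed: int,
                               cfg: TorcConfig | None = None) -> LabeledDataset:
    """Constructed reference with a user-supplied composition.

    This is how the benchmark strategies with the oracle target composition
    ``P^T`` and the uniform ``P-bar`` are expressed: same machinery as the
    estimated-composition resampling, different proportion vector.
    """
    cfg = cfg or TorcConfig()
    return resample_reference(ref_pool, comp, size, cfg, seed)


def _derive_child_seeds(seed: int) -> dict[str, int]:
    """Deterministic child seeds (< 2**31) for the three random stages."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    names = ("classifier_round1", "sampling", "classifier_round2")
    return {n: int(k.generate_state(1)[0] % (2**31)) for n, k in zip(names, kids)}


def _prepare(ref: LabeledDataset, target: CellMatrix, cfg: TorcConfig,
             spec: ClassifierSpec, seed: int):
    """Normalize, select features on the reference, and fit one classifier."""
    ref_norm = normalize_log(ref.matrix, cfg.normalize_scale)
    target_norm = normalize_log(target, cfg.normalize_scale)
    ref_ln = LabeledDataset(ref_norm, ref.labels, list(ref.type_names))
    n_feat = min(cfg.n_features, ref_norm.n_genes)
    sel = f_test_select(ref_ln, n_feat)
    ref_sel = LabeledDataset(ref_norm.subset_genes(sel.selected_gene_ids),
                             ref.labels, list(ref.type_names))
    fitted = clf_mod.fit(ref_sel, spec.with_seed(seed))
    probs = clf_mod.predict_proba(
        fitted, target_norm.subset_genes(sel.selected_gene_ids)
    )
    return fitted, probs


def run_torc(ref: LabeledDataset, target: CellMatrix, spec: ClassifierSpec,
             cfg: TorcConfig) -> TorcResult:
    """Run the full two-round procedure and return all diagnostics.

    Stages: intersect genes, normalize, F-test feature selection on the
    reference, round-1 fit/predict, entropy scoring, composition
    estimation, optional pool expansion, composition-matched resampling,
    round-2 retrain (with feature reselection by default), final
    prediction.
    """
    seeds = _derive_child_seeds(cfg.seed)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"TORC stage {name!r} failed: {exc}") from exc

    ref_m, target_m = stage("intersect_genes", intersect_genes, ref.matrix, target)
    ref = LabeledDataset(ref_m, ref.labels, list(ref.type_names))

    _, probs1 = stage(
        "round1", _prepare, ref, target_m, cfg, spec, seeds["classifier_round1"]
    )
    first_labels = predict_labels(probs1)
    ent = stage("entropy", entropy, probs1)
    comp_hat = stage(
        "estimate_composition", estimate_composition, probs1, cfg.composition_mode
    )

    if cfg.expand_pool:
        confident = stage("select_confident", select_confident, ent,
                          first_labels, cfg)
        pool = stage("expand_pool", expand_pool, ref, target_m, confident,
                     first_labels)
        added = confident
    else:
        pool, added = ref, []

    size = ref.n_cells if cfg.reference_size == "match_original" \
        else int(cfg.reference_size)
    constructed = stage("resample_reference", resample_reference, pool,
                        comp_hat, size, cfg, seeds["sampling"])

    if cfg.reselect_features:
        # full round-2 pipeline: re-normalize the constructed reference's
        # counts and redo feature selection on it
        _, probs2 = stage(
            "round2", _prepare, constructed, target_m, cfg, spec,
            seeds["classifier_round2"],
        )
    else:
        ref2_norm = stage("round2_normalize", normalize_log,
                          constructed.matrix, cfg.normalize_scale)
        # reuse the round-1 gene list instead of reselecting
        sel_genes = _round1_genes(ref, cfg)
        ref2 = LabeledDataset(ref2_norm.subset_genes(sel_genes),
                              constructed.labels, list(constructed.type_names))
        fitted2 = stage("round2_fit", clf_mod.fit, ref2,
                        spec.with_seed(seeds["classifier_round2"]))
        target_norm = stage("round2_normalize_target", normalize_log, target_m,
                            cfg.normalize_scale)
        probs2 = stage("round2_predict", clf_mod.predict_proba, fitted2,
                       target_norm.subset_genes(sel_genes))

    final_labels = predict_labels(probs2)
    return TorcResult(
        final_labels=final_labels,
        first_round_labels=first_labels,
        cell_ids=probs2.cell_ids.copy(),
        estimated_composition=comp_hat,
        entropies=ent,
        pool_added_cell_ids=[c for c in added],
        constructed_reference_composition=constructed.composition(),
        seed=cfg.seed,
        child_seeds=seeds,
    )


def _round1_genes(ref: LabeledDataset, cfg: TorcConfig) -> list[str]:
    ref_norm = normalize_log(ref.matrix, cfg.normalize_scale)
    sel = f_test_select(
        LabeledDataset(ref_norm, ref.labels, list(ref.type_names)),
        min(cfg.n_features, ref_norm.n_genes),
    )
    return sel.selected_gene_ids
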