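"""Canonical synthetic study scenarios.

Three ready-made experiments exercise the method end to end on simulated
data with known truth:

* :func:`reversal_benchmark` — the composition-reversal toy: four types,
  one mildly confusable pair whose odds are 4:1 in the reference but 1:4
  in the target, everything else matched.  Compares the four
  reference-construction strategies over paired seeds.
* :func:`domain_shift_benchmark` — matched compositions but a per-gene
  multiplicative batch effect on the target; measures the effect of
  entropy-gated reference-pool expansion.
* :func:`composition_recovery` — well-separated types, no shift; measures
  how closely the round-1 estimate recovers the target composition.

Problem sizes (2,000 cells per side, 500 genes, 200 selected features,
a single 64-unit hidden layer) keep each scenario to seconds per seed
while leaving the classifier comfortably converged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import ClassifierSpec
from .core import TorcConfig, estimate_composition, run_torc, _prepare
from .evaluation import compare_strategies, score
from .simulate import SimSpec, reversal_scenario, simulate_pair

__all__ = [
    "reversal_benchmark",
    "domain_shift_benchmark",
    "composition_recovery",
    "default_classifier_spec",
]

#: confusable pair retains 80% of its marker contrast
REVERSAL_SEPARATION = 0.8
REVERSAL_ODDS_REF = 4.0
REVERSAL_ODDS_TARGET = 0.25
DOMAIN_SHIFT_SD = 0.3
RECOVERY_TARGET_COMPOSITION = (0.4, 0.3, 0.2, 0.1)


def default_classifier_spec() -> ClassifierSpec:
    return ClassifierSpec(hidden_sizes=(64,), max_epochs=100)


def _scenario_cfg(seed: int = 0, **overrides) -> TorcConfig:
    kwargs = dict(n_features=200, seed=seed)
    kwargs.update(overrides)
    return TorcConfig(**kwargs)


def reversal_benchmark(n_seeds: int = 20, master_seed: int = 0,
                       sim_seed: int | None = None) -> pd.DataFrame:
    """Strategy comparison on the composition-reversal toy.

    Returns the summary frame of :func:`torc.evaluation.compare_strategies`
    (strategy, mean_accuracy, sd_accuracy, n_seeds) for the original
    reference and the three constructed-reference strategies.
    """
    if sim_seed is None:
        sim_seed = 1 + master_seed
    base = SimSpec(
        confusable_pairs=((0, 1, REVERSAL_SEPARATION),), seed=sim_seed
    )
    spec = reversal_scenario(base, (0, 1), REVERSAL_ODDS_REF,
                             REVERSAL_ODDS_TARGET)
    ref, target_truth = simulate_pair(spec)
    # the toy isolates composition: reference and target share one domain,
    # so the pool is not expanded here
    cfg = _scenario_cfg(expand_pool=False)
    _, summary = compare_strategies(
        ref, target_truth, ["original", "oracle", "estimated", "equal"],
        n_seeds=n_seeds, spec=default_classifier_spec(), cfg=cfg,
        master_seed=master_seed,
    )
    return summary


def domain_shift_benchmark(n_seeds: int = 20, master_seed: int = 0,
                           batch_effect_sd: float = DOMAIN_SHIFT_SD) -> pd.DataFrame:
    """Mean final accuracy with and without pool expansion under a
    batch-shifted target with matched compositions."""
    rows = []
    for s in range(n_seeds):
        sim = SimSpec(batch_effect_sd=batch_effect_sd,
                      seed=1000 + master_seed + s)
        ref, target_truth = simulate_pair(sim)
        for expand in (True, False):
            cfg = _scenario_cfg(seed=master_seed + s, expand_pool=expand)
            res = run_torc(ref, target_truth.matrix,
                           default_classifier_spec(), cfg)
            acc = score(target_truth.labels, res.final_labels).accuracy
            rows.append(("expand" if expand else "no_expand",
                         master_seed + s, acc))
    tidy = pd.DataFrame(rows, columns=["condition", "seed", "accuracy"])
    return (tidy.groupby("condition", sort=False)["accuracy"]
            .agg(mean_accuracy="mean", sd_accuracy="std").reset_index())


def composition_recovery(n_seeds: int = 20,
                         master_seed: int = 0) -> np.ndarray:
    """Per-seed max absolute error of the round-1 composition estimate on a
    well-separated, no-shift simulation."""
    truth = np.asarray(RECOVERY_TARGET_COMPOSITION)
    errors = []
    spec = default_classifier_spec()
    cfg = _scenario_cfg()
    for s in range(n_seeds):
        sim = SimSpec(target_composition=RECOVERY_TARGET_COMPOSITION,
                      seed=2000 + master_seed + s)
        ref, target_truth = simulate_pair(sim)
        _, probs = _prepare(ref, target_truth.matrix, cfg, spec,
                            master_seed + s)
        est = estimate_composition(probs, "hard")
        errors.append(float(np.max(np.abs(est.proportions - truth))))
    return np.asarray(errors)
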