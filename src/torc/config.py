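"""YAML run-configuration parsing with strict key validation.

Configs are nested mappings mirroring the library's dataclasses.  Unknown
keys are rejected with their full dotted path, so a typo like
``clasifier.seed`` fails loudly instead of silently using a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import ClassifierSpec
from .core import TorcConfig
from .simulate import SimSpec

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message carries the offending key path."""


@dataclass
class RunConfig:
    """Validated contents of a run/benchmark/simulate config file."""

    io: dict = field(default_factory=dict)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    torc: TorcConfig = field(default_factory=TorcConfig)
    simulate: SimSpec | None = None
    eval: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "torc_output"


_IO_KEYS = {
    "reference", "reference_labels", "target", "target_labels",
    "reference_mtx", "reference_genes", "reference_barcodes",
    "target_mtx", "target_genes", "target_barcodes", "format",
}
_EVAL_KEYS = {"strategies", "n_seeds"}
_CLS_KEYS = {
    "backend", "hidden_sizes", "max_epochs", "learning_rate", "batch_size",
    "early_stopping", "standardize", "seed",
}
_TORC_KEYS = {
    "expand_pool", "entropy_quantile", "per_type_gating", "composition_mode",
    "reference_size", "sample_with_replacement_fallback", "min_cells_per_type",
    "normalize_scale", "n_features", "reselect_features", "seed",
}
_SIM_KEYS = {
    "K", "n_genes", "n_marker_genes_per_type", "marker_logfc",
    "confusable_pairs", "ref_composition", "target_composition",
    "n_ref", "n_target", "batch_effect_sd", "baseline_mean", "dispersion",
    "seed",
}
_TOP_KEYS = {"io", "classifier", "torc", "simulate", "eval", "seed", "outdir"}


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(block) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown config key: {path}.{key}" if path else
                          f"unknown config key: {key}")


def _coerce(path: str, builder, kwargs: dict):
    try:
        return builder(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    _check_keys(raw, _TOP_KEYS, "")
    seed = int(raw.get("seed", 0))

    io_block = raw.get("io", {})
    _check_keys(io_block, _IO_KEYS, "io")
    eval_block = raw.get("eval", {})
    _check_keys(eval_block, _EVAL_KEYS, "eval")

    cls_block = dict(raw.get("classifier", {}))
    _check_keys(cls_block, _CLS_KEYS, "classifier")
    if "hidden_sizes" in cls_block:
        cls_block["hidden_sizes"] = tuple(cls_block["hidden_sizes"])
    cls_block.setdefault("seed", seed)
    spec = _coerce("classifier", ClassifierSpec, cls_block)

    torc_block = dict(raw.get("torc", {}))
    _check_keys(torc_block, _TORC_KEYS, "torc")
    torc_block.setdefault("seed", seed)
    cfg = _coerce("torc", TorcConfig, torc_block)

    sim = None
    if "simulate" in raw:
        sim_block = dict(raw["simulate"])
        _check_keys(sim_block, _SIM_KEYS, "simulate")
        for key in ("ref_composition", "target_composition"):
            if sim_block.get(key) is not None:
                sim_block[key] = tuple(sim_block[key])
        if "confusable_pairs" in sim_block:
            sim_block["confusable_pairs"] = tuple(
                tuple(p) for p in sim_block["confusable_pairs"]
            )
        sim_block.setdefault("seed", seed)
        sim = _coerce("simulate", SimSpec, sim_block)

    return RunConfig(
        io=dict(io_block),
        classifier=spec,
        torc=cfg,
        simulate=sim,
        eval=dict(eval_block),
        seed=seed,
        outdir=str(raw.get("outdir", "torc_output")),
    )
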