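"""Shared fixtures: small simulated datasets and fast classifier settings."""

from __future__ import annotations

import numpy as np
import pytest

from torc.classifier import ClassifierSpec
from torc.core import TorcConfig
from torc.simulate import SimSpec, simulate_pair
from torc.types import CellMatrix, LabeledDataset


@pytest.fixture(scope="session")
def fast_spec() -> ClassifierSpec:
    """A small MLP that trains in well under a second on the fixtures."""
    return ClassifierSpec(hidden_sizes=(32,), max_epochs=300, batch_size=64)


@pytest.fixture(scope="session")
def fast_cfg() -> TorcConfig:
    return TorcConfig(n_features=100, seed=0)


@pytest.fixture(scope="session")
def small_pair() -> tuple[LabeledDataset, LabeledDataset]:
    """A well-separated 3-type reference/target pair, 300 cells each."""
    spec = SimSpec(K=3, n_genes=200, n_marker_genes_per_type=15,
                   n_ref=300, n_target=300, seed=11)
    return simulate_pair(spec)


@pytest.fixture()
def tiny_labeled() -> LabeledDataset:
    """Deterministic 8-cell, 6-gene labeled dataset with two types."""
    rng = np.random.default_rng(5)
    values = rng.poisson(5.0, size=(8, 6)).astype(float) + 1.0
    m = CellMatrix(
        values,
        np.array([f"c{i}" for i in range(8)], dtype=object),
        np.array([f"g{i}" for i in range(6)], dtype=object),
        layer="counts",
    )
    labels = np.array(["A", "A", "A", "A", "B", "B", "B", "B"], dtype=object)
    return LabeledDataset(m, labels)


def random_prob_matrix(rng: np.random.Generator, n: int, k: int):
    """Random row-stochastic matrix (Dirichlet rows)."""
    return rng.dirichlet(np.ones(k), size=n)
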