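"""Pluggable classifier contract with an MLP default backend.

The reference-construction core only ever calls ``fit`` and
``predict_proba`` through :class:`FittedClassifier`, so any probabilistic
classifier can stand behind it.  The default backend is a multi-layer
perceptron (one hidden layer, ReLU, softmax output, Adam) with optional
per-gene standardization fit on the reference.  A nearest-centroid backend
is included both as the simplest possible plugin and as a fast option for
smoke tests.

Determinism contract: given the same data and ``spec.seed``, ``fit`` +
``predict_proba`` reproduce bitwise-identical outputs.  Cells are sorted by
cell id before fitting so results do not depend on input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np
from scipy.special import softmax
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .types import CellMatrix, LabeledDataset, ProbabilityMatrix

__all__ = [
    "ClassifierSpec",
    "ClassifierBackend",
    "FittedClassifier",
    "MLPBackend",
    "NearestCentroidBackend",
    "fit",
    "predict_proba",
    "predict_labels",
    "get_backend",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyper-parameters of the classification backend."""

    backend: str = "mlp"
    hidden_sizes: tuple[int, ...] = (100,)
    max_epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 200
    early_stopping: bool = True
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty and positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=int(seed))


class ClassifierBackend(Protocol):
    """What a plugin must implement.

    ``fit`` receives a feature matrix (cells x selected genes) and integer
    class codes; ``predict_proba`` returns one row-stochastic probability
    row per input cell, columns in class-code order.  Anything satisfying
    this protocol — including wrappers around external tools — can drive
    the two-round procedure unchanged.
    """

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int,
            spec: ClassifierSpec) -> None: ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...


class MLPBackend:
    """Default multi-layer perceptron backend (scikit-learn)."""

    def __init__(self) -> None:
        self._model: MLPClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int,
            spec: ClassifierSpec) -> None:
        self._model = MLPClassifier(
            hidden_layer_sizes=tuple(spec.hidden_sizes),
            activation="relu",
            solver="adam",
            learning_rate_init=spec.learning_rate,
            batch_size=min(spec.batch_size, X.shape[0]),
            max_iter=spec.max_epochs,
            # a 10% validation split below ~50 cells is too noisy to stop on
            early_stopping=spec.early_stopping and X.shape[0] >= 500,
            validation_fraction=0.1,
            n_iter_no_change=10,
            random_state=spec.seed,
        )
        self._model.fit(X, y)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        assert self._model is not None, "fit must be called first"
        proba = self._model.predict_proba(X)
        # sklearn orders columns by sorted class code, which is 0..K-1 here
        return proba


class NearestCentroidBackend:
    """Distance-to-centroid softmax classifier; the minimal valid plugin."""

    def __init__(self) -> None:
        self._centroids: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int,
            spec: ClassifierSpec) -> None:
        self._centroids = np.stack(
            [X[y == k].mean(axis=0) for k in range(n_classes)]
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        assert self._centroids is not None, "fit must be called first"
        d = np.linalg.norm(X[:, None, :] - self._centroids[None, :, :], axis=2)
        return softmax(-d, axis=1)


_BACKENDS: dict[str, type] = {
    "mlp": MLPBackend,
    "nearest_centroid": NearestCentroidBackend,
}


def get_backend(name: str) -> type:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown classifier backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None


def register_backend(name: str, cls: type) -> None:
    """Register an external :class:`ClassifierBackend` implementation."""
    _BACKENDS[name] = cls


@dataclass
class FittedClassifier:
    """A trained backend plus everything needed to apply it to new cells."""

    spec: ClassifierSpec
    type_names: list[str]
    selected_gene_ids: list[str]
    backend: object
    scaler: StandardScaler | None = None

    def predict_proba(self, target: CellMatrix) -> ProbabilityMatrix:
        return predict_proba(self, target)


def fit(ref: LabeledDataset, spec: ClassifierSpec) -> FittedClassifier:
    """Train a classifier on a feature-restricted, log-normalized reference.

    Type names are stored in sorted order; class codes follow that order.
    Rows are sorted by cell id before fitting so shuffled input files give
    identical results.
    """
    if len(ref.type_names) < 2:
        raise ValueError("cannot fit a classifier on a single-type reference")
    m = ref.matrix
    if not np.all(np.isfinite(m.values)):
        raise ValueError("reference contains non-finite values")
    order = np.argsort(m.cell_ids.astype(str), kind="stable")
    X = m.values[order]
    type_names = sorted(ref.type_names)
    code = {t: k for k, t in enumerate(type_names)}
    y = np.array([code[t] for t in ref.labels[order]], dtype=int)

    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        # constant genes carry no signal; avoid 0/0 without dropping them
        scaler.scale_[scaler.scale_ == 0.0] = 1.0
        X = scaler.transform(X)

    backend = get_backend(spec.backend)()
    backend.fit(X, y, len(type_names), spec)
    return FittedClassifier(
        spec=spec,
        type_names=type_names,
        selected_gene_ids=[str(g) for g in m.gene_ids],
        backend=backend,
        scaler=scaler,
    )


def predict_proba(clf: FittedClassifier, target: CellMatrix) -> ProbabilityMatrix:
    """Apply a fitted classifier; the target must carry exactly the
    classifier's selected genes in the same order."""
    got = [str(g) for g in target.gene_ids]
    if got != clf.selected_gene_ids:
        missing = sorted(set(clf.selected_gene_ids) - set(got))
        if missing:
            raise ValueError(
                f"target is missing classifier genes: {missing[:10]}"
            )
        raise ValueError("target genes must be in the classifier's gene order")
    X = target.values
    if clf.scaler is not None:
        X = clf.scaler.transform(X)
    probs = np.asarray(clf.backend.predict_proba(X), dtype=float)
    # clip tiny negative round-off and renormalize exactly
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(probs, target.cell_ids.copy(), list(clf.type_names))


def predict_labels(p: ProbabilityMatrix) -> np.ndarray:
    """Per-cell argmax labels; ties go to the first type in column order."""
    idx = np.argmax(p.probs, axis=1)  # argmax returns the first maximum
    names = np.asarray(p.type_names, dtype=object)
    return names[idx]
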