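"""Uniform interface over the six benchmark classifier families.

SVM / RF / k-NN / MLP are scikit-learn estimators; the two convolutional
families run on the in-repo NumPy backend.  ``build`` wires up the
published default hyperparameters, ``train`` optionally standardizes
features (fit on the training set only) and records a layout fingerprint
so a trained model refuses inputs with a different feature layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import _nn

__all__ = [
    "Family",
    "ClassifierSpec",
    "TrainedModel",
    "build",
    "train",
    "evaluate",
    "FAMILIES",
]

Family = Literal["SVM", "RF", "KNN", "MLP", "CNN1", "CNN2"]
FAMILIES: tuple[Family, ...] = ("SVM", "RF", "KNN", "MLP", "CNN1", "CNN2")
VECTOR_FAMILIES: tuple[Family, ...] = ("SVM", "RF", "KNN", "MLP", "CNN1")


@dataclass(frozen=True)
class ClassifierSpec:
    family: Family
    hyperparams: dict[str, Any] = field(default_factory=dict)
    input_form: Literal["vector", "matrix"] = "vector"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family: {self.family!r}")
        if self.family == "CNN2" and self.input_form != "matrix":
            raise ValueError("CNN2 requires matrix input")
        if self.family != "CNN2" and self.input_form != "vector":
            raise ValueError(f"{self.family} requires vector input")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    model: Any
    classes: np.ndarray
    fingerprint: tuple  # trailing feature shape seen at training time
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if tuple(X.shape[1:]) != self.fingerprint:
            raise ValueError(
                f"feature layout {tuple(X.shape[1:])} does not match the "
                f"training layout {self.fingerprint}"
            )
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_std
        if isinstance(self.model, _nn.Network):
            if X.ndim == 2:
                X = X[:, None, :]  # (B, 1, L)
            elif X.ndim == 3:
                X = X[:, None, :, :]  # (B, 1, J, N)
            return self.classes[self.model.predict(X)]
        return self.model.predict(X)


def _default_svm(hp: dict[str, Any], seed: int) -> GridSearchCV:
    c_grid = hp.get("c_grid", [0.1, 1.0, 10.0, 100.0])
    gamma_grid = hp.get("gamma_grid", list(np.logspace(-4, -1, 4)))
    cv = hp.get("cv", 3)
    return GridSearchCV(
        SVC(kernel="rbf"),
        {"C": c_grid, "gamma": gamma_grid},
        cv=cv,
        n_jobs=1,
    )


def _default_rf(hp: dict[str, Any], seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hp.get("n_estimators", 10),
        max_depth=hp.get("max_depth", 475),
        min_samples_split=hp.get("min_samples_split", 3),
        min_samples_leaf=hp.get("min_samples_leaf", 1),
        criterion=hp.get("criterion", "entropy"),
        random_state=seed,
    )


def _default_knn(hp: dict[str, Any], seed: int) -> KNeighborsClassifier:
    return KNeighborsClassifier(
        n_neighbors=hp.get("k", 20), metric="euclidean"
    )


def _default_mlp(hp: dict[str, Any], seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=hp.get("hidden", (1024, 512, 256)),
        activation="logistic",
        solver="adam",
        learning_rate_init=hp.get("lr", 1e-3),
        max_iter=hp.get("epochs", 50),
        batch_size=hp.get("batch_size", 32),
        random_state=seed,
    )


def _fc_head(sizes: tuple[int, ...], dropout: float) -> list[_nn.Layer]:
    head: list[_nn.Layer] = []
    for units in sizes:
        head += [_nn.Dense(units), _nn.Sigmoid()]
        if dropout > 0:
            head.append(_nn.Dropout(dropout))
    head.append(_nn.Dense(2))  # logits; softmax applied in the loss
    return head


class _LazyCNN:
    """Defers network construction until the input shape is known."""

    def __init__(self, family: Family, hp: dict[str, Any], seed: int) -> None:
        self.family, self.hp, self.seed = family, hp, seed
        self.net: _nn.Network | None = None

    def _build(self, in_shape: tuple) -> _nn.Network:
        hp = self.hp
        filters = hp.get("filters", 32)
        fc = tuple(hp.get("fc", (1024, 512, 256)))
        dropout = hp.get("dropout", 0.15)
        layers: list[_nn.Layer] = []
        if self.family == "CNN1":
            kernel = hp.get("kernel", 9)
            for _ in range(3):
                layers += [_nn.Conv1D(filters, kernel), _nn.ReLU()]
            layers.append(_nn.MaxPool1D())
        else:
            kernel = hp.get("kernel", 3)
            for _ in range(3):
                layers += [
                    _nn.Conv2D(filters, kernel),
                    _nn.ReLU(),
                    _nn.MaxPool2D(),
                ]
        layers.append(_nn.Flatten())
        layers += _fc_head(fc, dropout)
        return _nn.Network(
            layers,
            in_shape,
            seed=self.seed,
            lr=hp.get("lr", 1e-3),
            epochs=hp.get("epochs", 50),
            batch_size=hp.get("batch_size", 32),
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> _nn.Network:
        self.net = self._build(tuple(X.shape[1:]))
        return self.net.fit(X, y)


def build(spec: ClassifierSpec):
    """Instantiate an untrained model with the published defaults."""
    builders = {
        "SVM": _default_svm,
        "RF": _default_rf,
        "KNN": _default_knn,
        "MLP": _default_mlp,
    }
    if spec.family in builders:
        return builders[spec.family](spec.hyperparams, spec.seed)
    return _LazyCNN(spec.family, spec.hyperparams, spec.seed)


def train(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    standardize: bool = True,
) -> TrainedModel:
    """Fit a model; standardization statistics come from X only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if spec.family == "CNN2":
        if X.ndim != 3:
            raise ValueError(
                "CNN2 accepts only equal-row matrix input (n, J, N); "
                "ragged in-COI feature sets are unsupported"
            )
    elif X.ndim != 2:
        raise ValueError(f"{spec.family} expects vector input (n, d)")
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)  # constant features stay put
        X = (X - mean) / std
    model = build(spec)
    if isinstance(model, _LazyCNN):
        y_idx = np.searchsorted(classes, y)
        net = model.fit(
            X[:, None, :] if X.ndim == 2 else X[:, None, :, :], y_idx
        )
        fitted: Any = net
    else:
        fitted = model.fit(X, y)
    return TrainedModel(spec, fitted, classes, tuple(X.shape[1:]), mean, std)


def evaluate(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of correctly classified items, in [0, 1]."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(model.predict(X) == y))
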