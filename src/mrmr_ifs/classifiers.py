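"""Uniform adapter over the six classifier families of the IFS stage.

Families: SVM (RBF kernel), 1NN/3NN/5NN, decision tree, and a single
hidden-layer neural network. All operate on continuous expression values.
kNN uses Euclidean distance on raw features with no scaling — L1000 values
share a common scale; an optional per-feature z-scaling switch exists for
sensitivity analysis. Stochastic families (tree tie-breaks, net weights)
take an explicit recorded seed so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["FAMILIES", "ClassifierSpec", "fit_predict", "default_specs"]

FAMILIES = ("SVM", "1NN", "3NN", "5NN", "DecisionTree", "NeuralNet")

# defaults chosen to mirror the classical R implementations of each family:
# RBF SVM with cost 1 and gamma 1/n_features, kNN on raw Euclidean distance,
# CART-style tree, one hidden layer of 8 units for the net.
_DEFAULTS: dict[str, dict[str, Any]] = {
    "SVM": {"C": 1.0, "gamma": "auto", "kernel": "rbf"},
    "1NN": {"n_neighbors": 1},
    "3NN": {"n_neighbors": 3},
    "5NN": {"n_neighbors": 5},
    "DecisionTree": {"max_depth": None, "min_samples_split": 20},
    # single hidden layer trained with a quasi-Newton solver, the classical
    # small-sample formulation of this family
    "NeuralNet": {"hidden_layer_sizes": (8,), "solver": "lbfgs", "max_iter": 500},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters and seed.

    ``hyperparameters`` overrides the family defaults; the effective map is
    available via :meth:`effective_hyperparameters` and is what the run
    manifest records.
    """

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    z_scale: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; "
                             f"must be one of {FAMILIES}")

    def effective_hyperparameters(self) -> dict[str, Any]:
        hp = dict(_DEFAULTS[self.family])
        hp.update(self.hyperparameters)
        return hp

    def build(self):
        hp = self.effective_hyperparameters()
        if self.family == "SVM":
            return SVC(random_state=self.seed, **hp)
        if self.family in ("1NN", "3NN", "5NN"):
            return KNeighborsClassifier(algorithm="brute", **hp)
        if self.family == "DecisionTree":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        return MLPClassifier(random_state=self.seed, **hp)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "hyperparameters": self.effective_hyperparameters(),
            "seed": self.seed,
            "z_scale": self.z_scale,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ClassifierSpec":
        return cls(
            family=d["family"],
            hyperparameters=dict(d.get("hyperparameters", {})),
            seed=int(d.get("seed", 0)),
            z_scale=bool(d.get("z_scale", False)),
        )


def default_specs(seed: int = 0, families: tuple[str, ...] = FAMILIES
                  ) -> list[ClassifierSpec]:
    """One spec per requested family at the documented defaults."""
    return [ClassifierSpec(f, seed=seed) for f in families]


def fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
) -> np.ndarray:
    """Train on (train_X, train_y), return hard 0/1 predictions for test_X.

    Deterministic given the spec's seed. A single-class training set is an
    error: it signals a degenerate cross-validation fold.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test feature counts differ")
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set contains a single class")
    if spec.z_scale:
        mu = train_X.mean(axis=0)
        sd = train_X.std(axis=0)
        sd[sd == 0] = 1.0
        train_X = (train_X - mu) / sd
        test_X = (test_X - mu) / sd
    clf = spec.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(train_X, train_y)
        pred = clf.predict(test_X)
    return np.asarray(pred).astype(np.int64)
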