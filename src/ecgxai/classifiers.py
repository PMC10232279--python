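"""Tabular classifiers of reduced LVEF from ECG parameters.

Four model families are supported: random forest, support vector machine,
L2-penalised logistic regression, and a single-hidden-layer multi-layer
perceptron.  All expose predicted probabilities on [0, 1]; the binary call
uses a fixed cut-off (default 0.5, strict: a probability must *exceed* the
cut-off to call reduced LVEF).

Hyperparameter defaults are deliberately plain -- 500 trees, an RBF SVM with
Platt-calibrated probabilities, L2 logistic regression, one hidden layer of
64 units -- and every one is overridable through ``ModelSpec.hyperparameters``.
The SVM's probability calibration layer is a necessity of the family (margin
outputs are not probabilities), not a tuning choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import PairedDataset

FAMILIES = ("random_forest", "svm", "logistic_regression", "mlp")


@dataclass
class ModelSpec:
    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    balanced: bool = False      # optional class reweighting; off by default

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose one of {FAMILIES}")


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    cw = "balanced" if spec.balanced else None
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500),
            random_state=spec.seed, n_jobs=1, class_weight=cw, **hp)
    if spec.family == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=hp.pop("kernel", "rbf"), probability=True,
                        random_state=spec.seed, class_weight=cw, **hp)),
        ])
    if spec.family == "logistic_regression":
        return Pipeline([
            ("scale", StandardScaler()),
            ("logreg", LogisticRegression(
                penalty="l2", max_iter=hp.pop("max_iter", 2000),
                class_weight=cw, **hp)),
        ])
    if spec.family == "mlp":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64,)),
                max_iter=hp.pop("max_iter", 500),
                random_state=spec.seed, **hp)),
        ])
    raise AssertionError("unreachable")


@dataclass
class TrainedModel:
    """A fitted classifier with its frozen feature order."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]

    def predict_proba(self, X: Union[np.ndarray, PairedDataset]) -> np.ndarray:
        """Predicted probability of reduced LVEF, one value per record."""
        if isinstance(X, PairedDataset):
            if X.schema.names != self.feature_names:
                raise ValueError("dataset schema does not match the model's "
                                 "training feature order")
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(True)
        return proba[:, pos]

    def save(self, path) -> None:
        joblib.dump({"spec": self.spec, "estimator": self.estimator,
                     "feature_names": self.feature_names, "format": 1}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        return cls(blob["spec"], blob["estimator"], blob["feature_names"])


def train(ds: PairedDataset, spec: Optional[ModelSpec] = None) -> TrainedModel:
    """Fit a classifier family on a training split; deterministic given seed."""
    spec = spec or ModelSpec()
    y = ds.reduced
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    est = _build_estimator(spec)
    est.fit(ds.values, y)
    return TrainedModel(spec, est, list(ds.schema.names))


def classify(probs: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Binary call: True iff probability strictly exceeds the cut-off."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return probs > cutoff
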