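"""Extreme learning machine classifier.

A single-hidden-layer feed-forward network whose input weights and
biases are drawn randomly once (seeded) and never trained; the output
weights beta are the closed-form ridge-regularized least-squares
solution against one-hot class targets:

    H = act(X W + b),    beta = (H' H + ridge I)^-1 H' T

Prediction is the argmax over the class scores H beta. Training is
therefore a single linear solve, which is what makes the ELM cheap
enough to serve as the fitness function inside a wrapper feature
search as well as the final classifier.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.utils.validation import check_is_fitted

__all__ = ["ELMClassifier", "elm_train", "elm_predict", "evaluate"]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """ELM with sigmoid hidden units and a ridge-solved readout.

    Parameters
    ----------
    hidden_units : width H of the random hidden layer.
    ridge : Tikhonov regularization of the output solve.
    activation : one of {"sigmoid", "tanh", "relu"}.
    scale_input : standardize features with training mean/sd before
        the random projection (keeps the sigmoid out of saturation for
        arbitrarily scaled embeddings).
    random_state : seed for the input weights.
    """

    def __init__(self, hidden_units=500, ridge=1e-6, activation="sigmoid",
                 scale_input=True, random_state=None):
        self.hidden_units = hidden_units
        self.ridge = ridge
        self.activation = activation
        self.scale_input = scale_input
        self.random_state = random_state

    def _hidden(self, x: np.ndarray) -> np.ndarray:
        if self.scale_input:
            x = (x - self.center_) / self.scale_
        return _ACTIVATIONS[self.activation](x @ self.W_in_ + self.b_in_)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        d = X.shape[1]
        if self.scale_input:
            self.center_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.center_ = np.zeros(d)
            self.scale_ = np.ones(d)
        self.W_in_ = rng.uniform(-1.0, 1.0, size=(d, self.hidden_units))
        self.b_in_ = rng.uniform(-1.0, 1.0, size=self.hidden_units)
        h = self._hidden(X)
        t = np.eye(self.classes_.size)[y_idx]
        gram = h.T @ h + self.ridge * np.eye(self.hidden_units)
        self.beta_ = linalg.solve(gram, h.T @ t, assume_a="pos")
        self.n_features_in_ = d
        self.training_error_ = 1.0 - accuracy_score(y, self.predict(X))
        return self

    def decision_function(self, X):
        check_is_fitted(self, "beta_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return self._hidden(X) @ self.beta_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]


def elm_train(features, labels, hidden_units=500, ridge=1e-6, seed=None) -> ELMClassifier:
    """Train an ELM; thin functional wrapper over :class:`ELMClassifier`."""
    return ELMClassifier(
        hidden_units=hidden_units, ridge=ridge, random_state=seed
    ).fit(features, labels)


def elm_predict(model: ELMClassifier, features) -> np.ndarray:
    return model.predict(features)


def evaluate(y_true, y_pred, class_list=None) -> dict:
    """Accuracy, per-class recall and confusion matrix (rows = truth)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if class_list is None:
        class_list = np.unique(np.concatenate([y_true, y_pred]))
    class_list = np.asarray(class_list)
    for arr in (y_true, y_pred):
        if not np.isin(arr, class_list).all():
            raise ValueError("label outside class_list")
    cm = confusion_matrix(y_true, y_pred, labels=class_list)
    row_sums = cm.sum(axis=1)
    recall = np.divide(np.diag(cm), row_sums, out=np.zeros(len(class_list)),
                       where=row_sums > 0)
    return {
        "accuracy": float(np.trace(cm) / cm.sum()),
        "per_class_recall": recall.tolist(),
        "confusion_matrix": cm.tolist(),
        "classes": class_list.tolist(),
    }
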