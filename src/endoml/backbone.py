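"""Backbone embedding networks and BO-driven fine-tuning.

Two architectures sit behind one surface: a MobileNet-V2-style trunk
whose global-average-pool embedding is 1280-dimensional (the
production choice), and a small trainable CNN (``tiny_cnn``) for
desk-scale experiments. Fine-tuning follows the transfer-learning
pattern: the original classifier is dropped and replaced by
dropout + linear sized to the task's classes; for ``mobilenet_v2``
the frozen trunk provides features and the new head is trained, for
``tiny_cnn`` the whole network trains end-to-end. The three SGD
hyperparameters (learning rate, momentum, L2) live in a bounded box
and can be chosen by the Gaussian-process Bayesian optimizer with a
short proxy fine-tune as the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn
from ._mobilenet import NumpyMobileNetV2
from .bayesopt import SearchBox, optimize_ei

__all__ = [
    "BackboneSpec",
    "HyperParams",
    "HYPERPARAM_BOX",
    "BackboneModel",
    "build_backbone",
    "finetune",
    "tune_hyperparams",
    "extract_features",
    "BackboneFeatureExtractor",
]

_ARCHITECTURES = ("mobilenet_v2", "tiny_cnn")

# search box: learning rate and L2 on log scale, momentum linear
HYPERPARAM_BOX = SearchBox(
    lower=np.array([1e-4, 0.6, 1e-10]),
    upper=np.array([1.0, 0.8, 1e-2]),
    log_scale=np.array([True, False, True]),
)


@dataclass(frozen=True)
class BackboneSpec:
    architecture: str = "tiny_cnn"
    n_classes: int = 2
    embedding_width: int | None = None

    def __post_init__(self):
        if self.architecture not in _ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        width = self.embedding_width
        if self.architecture == "mobilenet_v2":
            if width not in (None, 1280):
                raise ValueError("mobilenet_v2 embedding width is fixed at 1280")
            width = 1280
        elif width is None:
            width = 64
        object.__setattr__(self, "embedding_width", int(width))

    @property
    def input_size(self) -> int:
        return 224 if self.architecture == "mobilenet_v2" else 64


@dataclass
class HyperParams:
    """SGD fine-tuning hyperparameters, constrained to the search box."""

    learning_rate: float = 0.01
    momentum: float = 0.7
    l2: float = 1e-5

    def __post_init__(self):
        lo, hi = HYPERPARAM_BOX.lower, HYPERPARAM_BOX.upper
        vec = np.array([self.learning_rate, self.momentum, self.l2])
        if np.any(vec < lo) or np.any(vec > hi):
            raise ValueError("hyperparameters outside the search box")

    def as_array(self) -> np.ndarray:
        return np.array([self.learning_rate, self.momentum, self.l2])

    @classmethod
    def from_array(cls, arr) -> "HyperParams":
        arr = np.asarray(arr, dtype=float)
        return cls(learning_rate=float(arr[0]), momentum=float(arr[1]),
                   l2=float(arr[2]))


class BackboneModel:
    """An embedding trunk plus a replaceable classification head."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        if spec.architecture == "mobilenet_v2":
            self.trunk = NumpyMobileNetV2(seed=seed)
            self.head = _nn.Sequential([
                _nn.Dropout(0.2, rng=np.random.default_rng(seed + 1)),
                _nn.Dense(spec.embedding_width, spec.n_classes, rng=rng),
                _nn.Softmax(),
            ])
            self.network = None
        else:
            w = spec.embedding_width
            self.network = _nn.Sequential([
                _nn.Conv2D(3, 16, stride=2, rng=rng),
                _nn.BatchNorm2D(16),
                _nn.ReLU(),
                _nn.MaxPool2D(),
                _nn.Conv2D(16, 32, stride=2, rng=rng),
                _nn.BatchNorm2D(32),
                _nn.ReLU(),
                _nn.Conv2D(32, w, stride=1, rng=rng),
                _nn.BatchNorm2D(w),
                _nn.ReLU(),
                _nn.GlobalAvgPool(),
                _nn.Dropout(0.2, rng=np.random.default_rng(seed + 1)),
                _nn.Dense(w, spec.n_classes, rng=rng),
                _nn.Softmax(),
            ])
            self._gap_index = 11  # layers up to and including GlobalAvgPool
        self.loss_history_: list[float] = []

    def prepare(self, images) -> np.ndarray:
        """Resize H x W x 3 frames (stack or ragged list) to NCHW input."""
        if isinstance(images, np.ndarray) and images.ndim == 3:
            images = [images]
        size = self.spec.input_size
        out = np.empty((len(images), 3, size, size))
        for i, img in enumerate(images):
            img = np.asarray(img, dtype=float)
            if img.shape[:2] != (size, size):
                img = resize(img, (size, size), order=1, mode="reflect",
                             anti_aliasing=True, preserve_range=True)
            out[i] = img.transpose(2, 0, 1)
        return out

    def features(self, images) -> np.ndarray:
        if len(images) == 0:
            return np.empty((0, self.spec.embedding_width))
        x = self.prepare(images)
        if self.spec.architecture == "mobilenet_v2":
            return self.trunk.features(x)
        return self.network.forward(x, train=False, upto=self._gap_index)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if self.spec.architecture == "mobilenet_v2":
            return self.head.forward(self.features(images), train=False)
        return self.network.forward(self.prepare(images), train=False)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)


def build_backbone(spec: BackboneSpec, seed: int = 0) -> BackboneModel:
    return BackboneModel(spec, seed=seed)


def finetune(model: BackboneModel, regions: np.ndarray, labels: np.ndarray,
             hp: HyperParams | None = None, epochs: int = 20,
             seed: int = 0) -> BackboneModel:
    """SGD fine-tune (head-only for mobilenet_v2, end-to-end for tiny_cnn)."""
    hp = hp or HyperParams()
    labels = np.asarray(labels, dtype=int)
    if len(regions) == 0:
        raise ValueError("empty region list")
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes")
    if model.spec.architecture == "mobilenet_v2":
        feats = model.features(regions)
        model.loss_history_ = _nn.train_network(
            model.head, feats, labels, epochs=epochs, lr=hp.learning_rate,
            momentum=hp.momentum, weight_decay=hp.l2, seed=seed)
    else:
        x = model.prepare(regions)
        model.loss_history_ = _nn.train_network(
            model.network, x, labels, epochs=epochs, lr=hp.learning_rate,
            momentum=hp.momentum, weight_decay=hp.l2, seed=seed)
    return model


def extract_features(model: BackboneModel, images: np.ndarray) -> np.ndarray:
    """N x D embedding matrix in input order (D = embedding width)."""
    return model.features(images)


def tune_hyperparams(train_images, train_labels, val_images, val_labels,
                     spec: BackboneSpec | None = None,
                     box: SearchBox = HYPERPARAM_BOX,
                     n_init: int = 5, n_iter: int = 5, seed: int = 0,
                     inner_epochs: int = 3) -> tuple[HyperParams, list[dict]]:
    """Choose (lr, momentum, L2) by BO on a short proxy fine-tune.

    The objective is the validation error rate after ``inner_epochs``
    of fine-tuning from a fresh seeded initialization.
    """
    spec = spec or BackboneSpec("tiny_cnn",
                                n_classes=int(np.unique(train_labels).size))
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("both splits must be non-empty")

    def objective(point):
        hp = HyperParams.from_array(point)
        model = build_backbone(spec, seed=seed)
        finetune(model, train_images, train_labels, hp,
                 epochs=inner_epochs, seed=seed)
        pred = model.predict(val_images)
        return float(np.mean(pred != np.asarray(val_labels)))

    best_point, _, history = optimize_ei(objective, box, n_init=n_init,
                                         n_iter=n_iter, seed=seed)
    return HyperParams.from_array(best_point), history


class BackboneFeatureExtractor(TransformerMixin, BaseEstimator):
    """Fit = fine-tune on labeled crops; transform = embed frames."""

    def __init__(self, architecture="tiny_cnn", embedding_width=None,
                 learning_rate=0.01, momentum=0.7, l2=1e-5, epochs=20,
                 tune=False, tune_budget=(4, 4), random_state=0):
        self.architecture = architecture
        self.embedding_width = embedding_width
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l2 = l2
        self.epochs = epochs
        self.tune = tune
        self.tune_budget = tune_budget
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        spec = BackboneSpec(self.architecture, n_classes=int(np.unique(y).size),
                            embedding_width=self.embedding_width)
        hp = HyperParams(self.learning_rate, self.momentum, self.l2)
        if self.tune:
            from sklearn.model_selection import train_test_split
            idx = np.arange(len(X))
            itr, iva = train_test_split(idx, test_size=0.3,
                                        random_state=self.random_state,
                                        stratify=y)
            xtr, xva = [X[i] for i in itr], [X[i] for i in iva]
            ytr, yva = y[itr], y[iva]
            hp, self.tune_history_ = tune_hyperparams(
                xtr, ytr, xva, yva, spec,
                n_init=self.tune_budget[0], n_iter=self.tune_budget[1],
                seed=self.random_state)
        self.hyperparams_ = hp
        self.model_ = build_backbone(spec, seed=self.random_state)
        finetune(self.model_, X, y, hp, epochs=self.epochs,
                 seed=self.random_state)
        self.embedding_width_ = spec.embedding_width
        return self

    def transform(self, X):
        return extract_features(self.model_, X)
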