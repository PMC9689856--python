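"""Deep saliency-map lesion segmentation and localization.

A compact 14-layer CNN (three strided 3x3 convolution blocks with
batch norm and ReLU, two 2x2 max pools, global average pooling, one
fully-connected layer and a softmax) is trained to classify frames.
The per-filter response maps of the *second* convolution on an input
frame are then scored by spatial variance, the clearest (top-k) maps
are averaged into a saliency map, the map is additively refined with
the contrast-enhanced frame, thresholded at its own mean, cleaned by
morphological closing + hole filling, and finally localized with a
Chan-Vese active contour per connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk
from skimage.segmentation import morphological_chan_vese
from skimage.transform import resize
from sklearn.base import BaseEstimator

from . import _nn

__all__ = [
    "SaliencyCNNSpec",
    "SaliencyTrainConfig",
    "LocalizedRegion",
    "build_saliency_cnn",
    "build_network",
    "train_saliency_cnn",
    "compute_saliency_map",
    "refine_map",
    "binarize",
    "morph_refine",
    "localize",
    "SaliencySegmenter",
]


@dataclass(frozen=True)
class SaliencyCNNSpec:
    """Declarative 14-layer architecture description.

    The layer order is fixed:
    conv-BN-ReLU-pool, conv-BN-ReLU-pool, conv-BN-ReLU, avgpool, FC,
    softmax; convolutions are 3x3 stride 2, pools 2x2 stride 2.
    """

    input_shape: tuple[int, int, int]
    n_classes: int
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    layers: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        h, w, c = self.input_shape
        if c != 3:
            raise ValueError("expected 3-channel input")
        if h % 32 or w % 32:
            raise ValueError("input sides must be divisible by 32 (stated strides)")
        order = (
            "conv", "batchnorm", "relu", "maxpool",
            "conv", "batchnorm", "relu", "maxpool",
            "conv", "batchnorm", "relu",
            "avgpool", "fc", "softmax",
        )
        object.__setattr__(self, "layers", order)

    @property
    def layer_count(self) -> int:
        return len(self.layers)

    def inventory(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.layers:
            counts[name] = counts.get(name, 0) + 1
        return counts


@dataclass
class SaliencyTrainConfig:
    """Training configuration; defaults follow the published recipe."""

    learning_rate: float = 0.05
    epochs: int = 100
    batch_size: int = 32
    momentum: float = 0.6
    dropout: float = 0.5
    optimizer: str = "sgd"
    seed: int = 0


@dataclass
class LocalizedRegion:
    """A localized lesion candidate: 0-based half-open box + crop.

    ``score`` is the region's saliency mass above its window baseline
    (overlap with the seed component when no saliency map was given);
    spurious background or specular regions score low.
    """

    box: tuple[int, int, int, int]     # (row0, col0, row1, col1)
    area: int
    contour_mask: np.ndarray
    crop: np.ndarray
    score: float = 0.0


def build_saliency_cnn(input_shape=(256, 256, 3), n_classes=2) -> SaliencyCNNSpec:
    """Construct (and validate) the 14-layer architecture spec."""
    return SaliencyCNNSpec(tuple(input_shape), int(n_classes))


def build_network(spec: SaliencyCNNSpec, seed: int = 0,
                  dropout: float = 0.5) -> _nn.Sequential:
    """Materialize the spec as a trainable network."""
    rng = np.random.default_rng(seed)
    c1, c2, c3 = spec.conv_channels
    layers = [
        _nn.Conv2D(3, c1, kernel=3, stride=2, rng=rng),
        _nn.BatchNorm2D(c1),
        _nn.ReLU(),
        _nn.MaxPool2D(),
        _nn.Conv2D(c1, c2, kernel=3, stride=2, rng=rng),
        _nn.BatchNorm2D(c2),
        _nn.ReLU(),
        _nn.MaxPool2D(),
        _nn.Conv2D(c2, c3, kernel=3, stride=2, rng=rng),
        _nn.BatchNorm2D(c3),
        _nn.ReLU(),
        _nn.GlobalAvgPool(),
        _nn.Dropout(dropout, rng=np.random.default_rng(seed + 1)),
        _nn.Dense(c3, spec.n_classes, rng=rng),
        _nn.Softmax(),
    ]
    net = _nn.Sequential(layers)
    net.spec = spec
    return net


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    return images.transpose(0, 3, 1, 2)


def train_saliency_cnn(images: np.ndarray, labels: np.ndarray,
                       cfg: SaliencyTrainConfig | None = None,
                       spec: SaliencyCNNSpec | None = None) -> _nn.Sequential:
    """Train the 14-layer CNN with SGD; seeded and reproducible."""
    cfg = cfg or SaliencyTrainConfig()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("image/label count mismatch")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    counts = np.bincount(labels)
    if (counts[counts > 0] < 2).any():
        raise ValueError("need at least two samples per class")
    spec = spec or build_saliency_cnn(images.shape[1:], classes.size)
    net = build_network(spec, seed=cfg.seed, dropout=cfg.dropout)
    x = _to_nchw(images)
    net.loss_history_ = _nn.train_network(
        net, x, labels, epochs=cfg.epochs, lr=cfg.learning_rate,
        momentum=cfg.momentum, batch_size=cfg.batch_size, seed=cfg.seed)
    return net


def _normalize01(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def compute_saliency_map(net: _nn.Sequential, image: np.ndarray,
                         top_k: int | None = None) -> np.ndarray:
    """Saliency from the second convolution's response maps.

    Different filters respond to the same structure with opposite
    polarity, so each map is first folded to its absolute deviation
    from its own median (conspicuity regardless of sign), min-max
    normalized, and scored by spatial variance; the top-k maps are
    averaged, upsampled to the image size, and normalized to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    x = _to_nchw(image)
    # forward through conv2 (layer index 4 in the fixed order)
    conv_seen = 0
    h = x
    for layer in net.layers:
        h = layer.forward(h, train=False)
        if isinstance(layer, _nn.Conv2D):
            conv_seen += 1
            if conv_seen == 2:
                break
    maps = h[0]  # (F, h', w')
    n_filters = maps.shape[0]
    if top_k is None:
        top_k = max(1, n_filters // 2)
    if top_k > n_filters:
        warnings.warn(f"top_k={top_k} exceeds filter count {n_filters}; clipped",
                      stacklevel=2)
        top_k = n_filters
    normed = np.stack([_normalize01(np.abs(m - np.median(m))) for m in maps])
    scores = normed.reshape(n_filters, -1).var(axis=1)
    chosen = np.argsort(-scores)[:top_k]
    merged = normed[chosen].mean(axis=0)
    up = resize(merged, image.shape[:2], order=1, mode="reflect",
                anti_aliasing=False, preserve_range=True)
    return _normalize01(up)


def refine_map(omap: np.ndarray, enhanced: np.ndarray) -> np.ndarray:
    """Add the enhanced frame's channel mean, renormalize to [0, 1]."""
    omap = np.asarray(omap, dtype=float)
    enhanced = np.asarray(enhanced, dtype=float)
    if enhanced.ndim != 3 or enhanced.shape[:2] != omap.shape:
        raise ValueError("saliency map and enhanced image shapes differ")
    return _normalize01(omap + enhanced.mean(axis=2))


def binarize(saliency: np.ndarray) -> np.ndarray:
    """Threshold at the map's arithmetic mean; ties go to foreground."""
    saliency = np.asarray(saliency, dtype=float)
    return (saliency >= saliency.mean()).astype(np.uint8)


def morph_refine(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Morphological closing followed by hole filling."""
    mask = np.asarray(mask).astype(bool)
    closed = closing(mask, disk(radius))
    filled = ndimage.binary_fill_holes(closed)
    return filled.astype(np.uint8)


def localize(mask: np.ndarray, image: np.ndarray, min_area: int = 64,
             cv_iterations: int = 50,
             score_map: np.ndarray | None = None) -> list[LocalizedRegion]:
    """Active-contour localization of each sufficiently large component.

    A Chan-Vese (morphological) contour is evolved per component,
    initialized from the component itself, within a padded window; if
    the contour collapses below ``min_area`` the raw component is
    kept. The contour splits the window into two intensity phases;
    when a ``score_map`` (the saliency map) is supplied the lesion is
    taken to be the connected piece holding the most saliency mass
    above the window's baseline (a tiny specular highlight or a huge
    dull background piece both lose under this score), otherwise the
    piece overlapping the initialization most. Regions are returned
    sorted by area, largest first.
    """
    mask = np.asarray(mask).astype(bool)
    image = np.asarray(image, dtype=float)
    gray = image.mean(axis=2) if image.ndim == 3 else image
    labeled, n = ndimage.label(mask)
    regions: list[LocalizedRegion] = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(comp)
        pad = 10
        r0 = max(rows.min() - pad, 0)
        r1 = min(rows.max() + 1 + pad, mask.shape[0])
        c0 = max(cols.min() - pad, 0)
        c1 = min(cols.max() + 1 + pad, mask.shape[1])
        window = gray[r0:r1, c0:c1]
        init = comp[r0:r1, c0:c1]
        evolved = morphological_chan_vese(window, num_iter=cv_iterations,
                                          init_level_set=init).astype(bool)
        # the contour may settle on either phase; examine both, piecewise
        candidates = []
        for phase in (evolved, ~evolved):
            lab_e, n_e = ndimage.label(phase)
            for le in range(1, n_e + 1):
                piece = lab_e == le
                if piece.sum() >= min_area:
                    candidates.append(piece)
        if score_map is not None:
            window_scores = score_map[r0:r1, c0:c1]
            baseline = window_scores.mean()
            key = lambda piece: float((window_scores[piece] - baseline).sum())
        else:
            key = lambda piece: int((piece & init).sum())
        refined = max(candidates, key=key) if candidates else init
        rr, cc = np.nonzero(refined)
        box = (int(rr.min() + r0), int(cc.min() + c0),
               int(rr.max() + 1 + r0), int(cc.max() + 1 + c0))
        full = np.zeros_like(mask)
        full[r0:r1, c0:c1] = refined
        crop = image[box[0]:box[2], box[1]:box[3]]
        regions.append(LocalizedRegion(box=box, area=int(refined.sum()),
                                       contour_mask=full, crop=crop,
                                       score=float(key(refined))))
    regions.sort(key=lambda r: -r.area)
    return regions


class SaliencySegmenter(BaseEstimator):
    """Trainable saliency segmenter with an sklearn-style surface.

    ``fit(images, labels)`` trains the 14-layer CNN on (enhanced)
    frames; ``transform(images)`` returns refined binary masks; and
    ``localize_regions`` yields cropped lesion candidates per frame.
    """

    def __init__(self, learning_rate=0.05, epochs=100, batch_size=32,
                 momentum=0.6, dropout=0.5, top_k=None, closing_radius=3,
                 min_area=64, random_state=0):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.momentum = momentum
        self.dropout = dropout
        self.top_k = top_k
        self.closing_radius = closing_radius
        self.min_area = min_area
        self.random_state = random_state

    def fit(self, X, y):
        cfg = SaliencyTrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, momentum=self.momentum,
            dropout=self.dropout, seed=self.random_state)
        self.network_ = train_saliency_cnn(np.asarray(X), np.asarray(y), cfg)
        self.spec_ = self.network_.spec
        return self

    def saliency_map(self, image, enhanced=None):
        omap = compute_saliency_map(self.network_, image, self.top_k)
        if enhanced is not None:
            omap = refine_map(omap, enhanced)
        return omap

    def segment(self, image, enhanced=None):
        omap = self.saliency_map(image, enhanced)
        return morph_refine(binarize(omap), self.closing_radius)

    def transform(self, X, enhanced=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        enh = enhanced if enhanced is not None else [None] * len(X)
        return np.stack([self.segment(img, e) for img, e in zip(X, enh)])

    def localize_regions(self, image, enhanced=None):
        omap = self.saliency_map(image, enhanced)
        mask = morph_refine(binarize(omap), self.closing_radius)
        return localize(mask, image, self.min_area, score_map=omap)

    def segment_localized(self, image, enhanced=None, score_share=0.25):
        """Union of the contour-refined localized regions (full chain).

        Regions whose saliency-excess score falls below
        ``score_share`` of the best region's are treated as spurious
        and excluded from the segmentation mask.
        """
        regions = self.localize_regions(image, enhanced)
        out = np.zeros(np.asarray(image).shape[:2], dtype=np.uint8)
        if not regions:
            return out
        cutoff = score_share * max(r.score for r in regions)
        for region in regions:
            if region.score >= cutoff and region.score > 0:
                out |= region.contour_mask.astype(np.uint8)
        return out
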