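"""Minimal NumPy neural-network kit with manual backpropagation.

Supports exactly the layer vocabulary the saliency CNN and the tiny
backbone need: strided 3x3 convolutions (im2col), 2x2 max pooling,
batch normalization, ReLU / ReLU6, global average pooling, dense
layers, dropout, and a fused softmax cross-entropy loss, trained with
SGD + momentum + L2 weight decay.

Array convention is NCHW throughout. All randomness flows through
``numpy.random.Generator`` instances so that seeded training is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Dropout",
    "Softmax",
    "Sequential",
    "SGD",
    "softmax_cross_entropy",
    "train_network",
]


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    # edge padding: a constant image stays constant under convolution,
    # so feature maps carry no spurious border structure
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")


class Conv2D(Layer):
    """3x3 (or kxk) convolution with 'same'-style padding and stride.

    Forward/backward use im2col so the heavy lifting is one matmul.
    He-normal initialization.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k = int(kernel)
        self.stride = int(stride)
        self.pad = (self.k - 1) // 2
        scale = np.sqrt(2.0 / (c_in * self.k * self.k))
        self.W = rng.normal(0.0, scale, size=(c_in * self.k * self.k, c_out))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def _im2col(self, xp: np.ndarray):
        # xp: padded (N, C, Hp, Wp) -> (N, Ho, Wo, C*k*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win[:, :, :: self.stride, :: self.stride, :, :]
        return cols

    def forward(self, x, train=False):
        xp = _pad_hw(x, self.pad)
        cols = self._im2col(xp)  # (N, C, Ho, Wo, k, k)
        n, c, ho, wo = cols.shape[:4]
        flat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, -1)
        out = flat @ self.W + self.b
        if train:
            self._cache = (x.shape, flat)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        xshape, flat = self._cache
        n, c, h, w = xshape
        g = grad.transpose(0, 2, 3, 1)  # (N, Ho, Wo, F)
        ho, wo = g.shape[1], g.shape[2]
        self.gW[...] = flat.reshape(-1, flat.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        self.gb[...] = g.sum(axis=(0, 1, 2))
        gflat = g @ self.W.T  # (N, Ho, Wo, C*k*k)
        gcols = gflat.reshape(n, ho, wo, c, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad))
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[:, :, :, :, i, j]
        p = self.pad
        if not p:
            return gx
        # fold the pad-region gradient back onto the replicated edge pixels
        core = gx[:, :, p : p + h, p : p + w].copy()
        core[:, :, 0, :] += gx[:, :, :p, p : p + w].sum(axis=2)
        core[:, :, -1, :] += gx[:, :, p + h :, p : p + w].sum(axis=2)
        core[:, :, :, 0] += gx[:, :, p : p + h, :p].sum(axis=3)
        core[:, :, :, -1] += gx[:, :, p : p + h, p + w :].sum(axis=3)
        core[:, :, 0, 0] += gx[:, :, :p, :p].sum(axis=(2, 3))
        core[:, :, 0, -1] += gx[:, :, :p, p + w :].sum(axis=(2, 3))
        core[:, :, -1, 0] += gx[:, :, p + h :, :p].sum(axis=(2, 3))
        core[:, :, -1, -1] += gx[:, :, p + h :, p + w :].sum(axis=(2, 3))
        return core

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.ggamma = np.zeros(channels)
        self.gbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if train:
            self._cache = (xhat, std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.ggamma[...] = (grad * xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        g = grad * self.gamma[None, :, None, None]
        gm = g.mean(axis=axes)
        gxm = (g * xhat).mean(axis=axes)
        gx = (g - gm[None, :, None, None] - xhat * gxm[None, :, None, None]) / std[None, :, None, None]
        return gx

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]


class ReLU(Layer):
    def __init__(self, cap: float | None = None):
        self.cap = cap  # cap=6.0 gives ReLU6
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if self.cap is not None:
            out = np.minimum(out, self.cap)
        if train:
            self._mask = (x > 0) if self.cap is None else ((x > 0) & (x < self.cap))
        return out

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; odd sizes are -inf padded."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
        n, c, h2, w2 = x.shape
        ho, wo = h2 // 2, w2 // 2
        tiles = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        idx = tiles.argmax(axis=-1)
        out = np.take_along_axis(tiles, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = ((n, c, h, w), (h2, w2), idx)
        return out

    def backward(self, grad):
        (n, c, h, w), (h2, w2), idx = self._cache
        ho, wo = h2 // 2, w2 // 2
        gt = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(gt, idx[..., None], grad[..., None], axis=-1)
        gx = gt.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2)
        return gx[:, :, :h, :w]


class GlobalAvgPool(Layer):
    """Average pooling over the full spatial extent -> (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class Dropout(Layer):
    """Inverted dropout; identity at inference. Draws from its own rng."""

    def __init__(self, rate=0.5, rng=None):
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Softmax(Layer):
    """Standalone softmax; during training the fused loss bypasses it."""

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, grad):  # pragma: no cover - training uses fused loss
        return grad


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, upto: int | None = None):
        for layer in self.layers[:upto]:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad, skip_last: int = 0):
        layers = self.layers[: len(self.layers) - skip_last] if skip_last else self.layers
        for layer in reversed(layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def predict_proba(self, x):
        return self.forward(x, train=False)

    def predict(self, x):
        return self.predict_proba(x).argmax(axis=1)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), y] + 1e-12).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params, grads, lr=0.01, momentum=0.0, weight_decay=0.0):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= self.lr * (g + self.weight_decay * p)
            p += v


def train_network(
    net: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    lr: float,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
    batch_size: int = 32,
    seed: int = 0,
    softmax_is_last: bool = True,
) -> list[float]:
    """SGD training loop; returns the per-epoch mean loss history.

    When the network's final layer is a Softmax the fused
    softmax-cross-entropy loss is applied to the pre-softmax logits.
    """
    rng = np.random.default_rng(seed)
    for i, layer in enumerate(net.layers):  # dropout reseeded per training run
        if isinstance(layer, Dropout):
            layer.rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
    opt = SGD(net.params(), net.grads(), lr=lr, momentum=momentum, weight_decay=weight_decay)
    skip = 1 if softmax_is_last else 0
    n = x.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            upto = len(net.layers) - skip if skip else None
            logits = net.forward(x[idx], train=True, upto=upto)
            loss, grad = softmax_cross_entropy(logits, y[idx])
            net.backward(grad, skip_last=skip)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    recalibrate_batchnorm(net, x)
    return history


def recalibrate_batchnorm(net: Sequential, x: np.ndarray) -> None:
    """Set BN running statistics from the final weights' activations.

    With few, large steps the exponentially averaged statistics lag the
    weights badly; one pass over the training set pins them to the
    converged network.
    """
    h = x
    for layer in net.layers:
        if isinstance(layer, BatchNorm2D):
            layer.running_mean = h.mean(axis=(0, 2, 3))
            layer.running_var = h.var(axis=(0, 2, 3))
        h = layer.forward(h, train=False)
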