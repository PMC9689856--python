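"""Forward-only NumPy MobileNet-V2 feature extractor.

The standard inverted-residual architecture (stem conv, seven
bottleneck stages, 1x1 head conv to 1280 channels, global average
pooling). Weights are He-initialized from a seed; batch-norm running
statistics are set once by a seeded calibration pass (LSUV-style) and
then frozen, so feature extraction is a deterministic function of the
seed. Used as the 1280-dimensional embedding backbone; training of
the classification head happens outside, on the pooled features.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NumpyMobileNetV2"]

_BOTTLENECKS = [
    # (expansion t, out channels c, repeats n, first stride s)
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def _relu6(x):
    return np.clip(x, 0.0, 6.0)


class _BN:
    """Inference-only batch norm; stats set once during calibration."""

    def __init__(self, channels, eps=1e-5):
        self.mean = np.zeros(channels)
        self.var = np.ones(channels)
        self.eps = eps

    def __call__(self, x, calibrate=False):
        if calibrate:
            self.mean = x.mean(axis=(0, 2, 3))
            self.var = x.var(axis=(0, 2, 3)) + 1e-8
        scale = 1.0 / np.sqrt(self.var + self.eps)
        return (x - self.mean[None, :, None, None]) * scale[None, :, None, None]


class _Conv3x3:
    def __init__(self, c_in, c_out, stride, rng):
        self.stride = stride
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0, scale, size=(c_in * 9, c_out))

    def __call__(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win[:, :, :: self.stride, :: self.stride]
        ho, wo = cols.shape[2], cols.shape[3]
        flat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, -1)
        return (flat @ self.w).transpose(0, 3, 1, 2)


class _Depthwise3x3:
    def __init__(self, channels, stride, rng):
        self.stride = stride
        self.w = rng.normal(0, np.sqrt(2.0 / 9), size=(channels, 3, 3))

    def __call__(self, x):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win[:, :, :: self.stride, :: self.stride]
        return np.einsum("nchwij,cij->nchw", cols, self.w, optimize=True)


class _Conv1x1:
    def __init__(self, c_in, c_out, rng):
        self.w = rng.normal(0, np.sqrt(2.0 / c_in), size=(c_in, c_out))

    def __call__(self, x):
        return np.einsum("nchw,cf->nfhw", x, self.w, optimize=True)


class _Bottleneck:
    """Inverted residual: expand (1x1) -> depthwise -> project (linear)."""

    def __init__(self, c_in, c_out, expansion, stride, rng):
        hidden = c_in * expansion
        self.expand = _Conv1x1(c_in, hidden, rng) if expansion != 1 else None
        self.bn_e = _BN(hidden) if self.expand else None
        self.depthwise = _Depthwise3x3(hidden, stride, rng)
        self.bn_d = _BN(hidden)
        self.project = _Conv1x1(hidden, c_out, rng)
        self.bn_p = _BN(c_out)
        self.residual = stride == 1 and c_in == c_out

    def __call__(self, x, calibrate=False):
        h = x
        if self.expand is not None:
            h = _relu6(self.bn_e(self.expand(h), calibrate))
        h = _relu6(self.bn_d(self.depthwise(h), calibrate))
        h = self.bn_p(self.project(h), calibrate)
        return x + h if self.residual else h


class NumpyMobileNetV2:
    """Seeded random-weight MobileNet-V2 trunk; ``features`` -> N x 1280."""

    embedding_width = 1280
    input_size = 224

    def __init__(self, seed: int = 0, calibration_images: int = 2):
        rng = np.random.default_rng(seed)
        self.stem = _Conv3x3(3, 32, stride=2, rng=rng)
        self.bn_stem = _BN(32)
        self.blocks: list[_Bottleneck] = []
        c_in = 32
        for t, c, n, s in _BOTTLENECKS:
            for i in range(n):
                self.blocks.append(
                    _Bottleneck(c_in, c, t, s if i == 0 else 1, rng))
                c_in = c
        self.head = _Conv1x1(c_in, self.embedding_width, rng)
        self.bn_head = _BN(self.embedding_width)
        calib = rng.random((calibration_images, 3, self.input_size, self.input_size))
        self._forward(calib, calibrate=True)

    def _forward(self, x: np.ndarray, calibrate: bool = False) -> np.ndarray:
        h = _relu6(self.bn_stem(self.stem(x), calibrate))
        for block in self.blocks:
            h = block(h, calibrate=calibrate)
        h = _relu6(self.bn_head(self.head(h), calibrate))
        return h.mean(axis=(2, 3))

    def features(self, images_nchw: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Pooled 1280-dim embeddings for a (N, 3, 224, 224) batch."""
        x = np.asarray(images_nchw, dtype=float)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected (N, 3, H, W) input")
        out = [self._forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty((0, self.embedding_width))
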