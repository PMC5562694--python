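"""A compact convolutional neural network for 32×32 paired-ROI scoring.

The network follows a fixed five-main-layer design: two 3×3 convolution
layers of 16 kernels (each followed by ReLU, 2×2 max pooling and local
response normalization across channels), two 3×3 locally-connected layers
of 16 kernels, and one fully-connected layer feeding a 2-way softmax. A
locally-connected layer performs the same sliding-window operation as a
convolution except that an independent kernel is learned at every spatial
location (no weight sharing) — tying all of its per-location kernels to a
single kernel reproduces the corresponding convolution exactly, which is
tested.

Everything is plain NumPy with explicit forward/backward passes and
seeded SGD with momentum, so training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass
class CNNConfig:
    """Architecture and optimizer hyperparameters."""

    input_shape: Tuple[int, int] = (32, 32)
    n_kernels: int = 16
    kernel_size: int = 3
    n_classes: int = 2
    lrn_n: int = 5
    lrn_alpha: float = 1e-4
    lrn_beta: float = 0.75
    lrn_k: float = 2.0
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    dtype: str = "float32"   # float64 available for gradient checking

    def __post_init__(self) -> None:
        if self.n_kernels < 1 or self.kernel_size < 1 or self.n_classes < 2:
            raise ValueError("malformed CNN configuration")
        if any(s % 4 != 0 for s in self.input_shape):
            raise ValueError("input sides must be divisible by 4 (two 2x2 poolings)")


# ------------------------------------------------------------------ layers

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*k*k) patches ('same' geometry)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    win = np.transpose(win, (0, 2, 3, 1, 4, 5))
    n, h, w = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, h, w, -1)


def _col2im(dcols: np.ndarray, c: int, k: int, pad: int,
            shape_hw: Tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n = dcols.shape[0]
    h, w = shape_hw
    dcols = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += np.transpose(
                dcols[:, :, :, :, di, dj], (0, 3, 1, 2))
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3×3 'same' convolution with one shared kernel set."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape_hw = x.shape[2:]
        self._cols = _im2col(x, self.k, self.pad)
        out = self._cols @ self.W.reshape(self.c_out, -1).T + self.b
        return np.transpose(out, (0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyt = np.transpose(dy, (0, 2, 3, 1))          # (N, H, W, Cout)
        f = self.c_in * self.k * self.k
        self.grads[0][...] = (dyt.reshape(-1, self.c_out).T
                              @ self._cols.reshape(-1, f)).reshape(self.W.shape)
        self.grads[1][...] = dyt.sum(axis=(0, 1, 2))
        dcols = dyt @ self.W.reshape(self.c_out, -1)
        return _col2im(dcols, self.c_in, self.k, self.pad, self._shape_hw)


class LocallyConnected2D(Layer):
    """Convolution-like layer with an independent kernel at every location."""

    def __init__(self, c_in: int, c_out: int, k: int, hw: Tuple[int, int],
                 rng: np.random.Generator, dtype=np.float64):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad = k // 2
        h, w = hw
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale,
                            size=(h, w, c_in * k * k, c_out)).astype(dtype)
        self.b = np.zeros((h, w, c_out), dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def tie_to_convolution(self, conv_w: np.ndarray, conv_b: np.ndarray) -> None:
        """Set every per-location kernel equal to one shared kernel set;
        the layer then computes exactly the corresponding convolution."""
        self.W[...] = conv_w.reshape(conv_w.shape[0], -1).T[None, None]
        self.b[...] = conv_b[None, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape_hw = x.shape[2:]
        self._cols = _im2col(x, self.k, self.pad)
        colsT = np.ascontiguousarray(self._cols.transpose(1, 2, 0, 3))  # (h,w,n,f)
        self._colsT = colsT
        out = colsT @ self.W + self.b[:, :, None, :]  # (h, w, n, o)
        return np.ascontiguousarray(out.transpose(2, 3, 0, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dytT = np.ascontiguousarray(dy.transpose(2, 3, 0, 1))  # (h, w, n, o)
        self.grads[0][...] = self._colsT.transpose(0, 1, 3, 2) @ dytT
        self.grads[1][...] = dytT.sum(axis=2)
        dcols = (dytT @ self.W.transpose(0, 1, 3, 2)).transpose(2, 0, 1, 3)
        return _col2im(dcols, self.c_in, self.k, self.pad, self._shape_hw)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        onehot = np.eye(4, dtype=dy.dtype)[self._arg]       # (n,c,h2,w2,4)
        d = onehot * dy[..., None]
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class LRN(Layer):
    """Local response normalization across channels (AlexNet-style):
    ``y_c = x_c / (k + alpha/n * sum_{c' in window} x_{c'}^2)^beta``."""

    def __init__(self, n: int = 5, alpha: float = 1e-4, beta: float = 0.75,
                 k: float = 2.0):
        self.n, self.alpha, self.beta, self.k = n, alpha, beta, k

    def _window_sum(self, a: np.ndarray) -> np.ndarray:
        half = self.n // 2
        c = a.shape[1]
        pad = np.pad(a, ((0, 0), (half, half), (0, 0), (0, 0)))
        csum = np.cumsum(pad, axis=1)
        csum = np.concatenate([np.zeros_like(csum[:, :1]), csum], axis=1)
        return csum[:, self.n:self.n + c] - csum[:, :c]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._den = self.k + (self.alpha / self.n) * self._window_sum(x ** 2)
        self._scale = self._den ** (-self.beta)
        return x * self._scale

    def backward(self, dy: np.ndarray) -> np.ndarray:
        inner = dy * self._x * self._den ** (-self.beta - 1.0)
        return dy * self._scale - (2.0 * self.alpha * self.beta / self.n) \
            * self._x * self._window_sum(inner)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


# ------------------------------------------------------------------ network

class Network:
    """A feed-forward layer stack with softmax cross-entropy training."""

    def __init__(self, layers: Sequence[Layer], cfg: CNNConfig):
        self.layers = list(layers)
        self.cfg = cfg

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(x)
        n = x.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        d = probs.copy()
        d[np.arange(n), y] -= 1.0
        d /= n
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return loss

    @property
    def param_layers(self) -> List[Layer]:
        return [l for l in self.layers if l.params]


def build_cnn(cfg: CNNConfig) -> Network:
    """Assemble the fixed layer sequence (conv → pool → norm, twice, then
    two locally-connected layers, then the fully-connected output)."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.input_shape
    nk, k = cfg.n_kernels, cfg.kernel_size
    dt = np.dtype(cfg.dtype).type
    lrn = dict(n=cfg.lrn_n, alpha=cfg.lrn_alpha, beta=cfg.lrn_beta, k=cfg.lrn_k)
    layers: List[Layer] = [
        Conv2D(1, nk, k, rng, dt), ReLU(), MaxPool2x2(), LRN(**lrn),
        Conv2D(nk, nk, k, rng, dt), ReLU(), MaxPool2x2(), LRN(**lrn),
        LocallyConnected2D(nk, nk, k, (h // 4, w // 4), rng, dt), ReLU(),
        LocallyConnected2D(nk, nk, k, (h // 4, w // 4), rng, dt), ReLU(),
        Flatten(), Dense((h // 4) * (w // 4) * nk, cfg.n_classes, rng, dt),
    ]
    return Network(layers, cfg)


@dataclass
class TrainedCNN:
    """A trained network plus the input standardization it was fitted with."""

    kind: str
    net: Network
    input_mean: float
    input_sd: float
    loss_trace: List[float]
    config: CNNConfig

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        x = self._prepare(patches)
        out = np.empty((x.shape[0], self.config.n_classes))
        for i in range(0, x.shape[0], 256):
            out[i:i + 256] = self.net.predict_proba(x[i:i + 256])
        return out

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=float)
        if x.ndim == 2:
            x = x[None]
        x = (x - self.input_mean) / self.input_sd
        return x[:, None, :, :].astype(self.config.dtype)


def train_cnn(cfg: CNNConfig, patches: np.ndarray, labels: np.ndarray
              ) -> TrainedCNN:
    """Seeded mini-batch SGD training on labeled 32×32 paired ROIs.

    ``labels`` are 1 for complete response (T0). Inputs are standardized
    with the training set's global mean/SD. Deterministic given
    ``cfg.seed``.
    """
    x = np.asarray(patches, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 3 or x.shape[1:] != tuple(cfg.input_shape):
        raise ValueError(f"patches must be (N, {cfg.input_shape[0]}, "
                         f"{cfg.input_shape[1]})")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training set")

    mu = float(x.mean())
    sd = float(x.std()) or 1.0
    xs = ((x - mu) / sd)[:, None, :, :].astype(cfg.dtype)

    net = build_cnn(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    velocity = [[np.zeros_like(p) for p in layer.params]
                for layer in net.param_layers]
    trace: List[float] = []
    n = xs.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = net.loss_and_backward(xs[idx], y[idx])
            losses.append(loss)
            for layer, vel in zip(net.param_layers, velocity):
                for p, g, v in zip(layer.params, layer.grads, vel):
                    if cfg.weight_decay:
                        g = g + cfg.weight_decay * p
                    v *= cfg.momentum
                    v -= cfg.lr * g
                    p += v
        trace.append(float(np.mean(losses)))
    return TrainedCNN(kind="cnn", net=net, input_mean=mu, input_sd=sd,
                      loss_trace=trace, config=cfg)
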