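"""Minimal NumPy neural-network engine for the patch autoencoders.

Implements exactly the layer vocabulary the segmentation models need —
2D convolution and transposed convolution with TensorFlow-style "same"
padding, batch normalization, leaky ReLU, a dense bottleneck, dropout —
together with analytic backpropagation, a binary cross-entropy-from-logits
loss, and Adam with the AMSGrad correction.  Tensors are NCHW.  Every
layer's backward pass is verified against finite differences in the test
suite, so the engine can serve as a trustworthy base for the
patch-segmentation models without any deep-learning framework dependency.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "LeakyReLU",
    "Dense",
    "Dropout",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "bce_with_logits_grad",
]

_DTYPE = np.float32


def _same_pads(in_size: int, out_size: int, k: int, stride: int) -> tuple[int, int]:
    """TensorFlow 'same' padding: smaller pad before, larger after."""
    total = max((out_size - 1) * stride + k - in_size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, k: int, stride: int, pads) -> np.ndarray:
    """Unfold x (N,C,H,W) into a (N*OH*OW, C*k*k) matrix for BLAS matmuls."""
    (pt, pb), (pl, pr) = pads
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * k * k), (n, oh, ow)


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pads, cols=None):
    """Correlate x (N,C,H,W) with w (O,C,k,k); returns ((N,O,H',W'), cols)."""
    k = w.shape[2]
    if cols is None:
        cols, shape = _im2col(x, k, stride, pads)
    else:
        cols, shape = cols
    n, oh, ow = shape
    o = w.shape[0]
    y = cols @ w.reshape(o, -1).T
    return y.reshape(n, oh, ow, o).transpose(0, 3, 1, 2), (cols, shape)


def _conv_bwd_weights(cols, dy: np.ndarray, w_shape) -> np.ndarray:
    """dL/dw from cached input columns and dy (N,O,OH,OW)."""
    o = dy.shape[1]
    dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, o)
    return (dy_mat.T @ cols[0]).reshape(w_shape)


def _conv_bwd_data(dy: np.ndarray, w: np.ndarray, stride: int, pads, in_hw) -> np.ndarray:
    """Gradient w.r.t. the conv input; also the forward map of ConvTranspose2D."""
    n, o, oh, ow = dy.shape
    c, k = w.shape[1], w.shape[2]
    (pt, _pb), (pl, _pr) = pads
    hp = in_hw[0] + pads[0][0] + pads[0][1]
    wp = in_hw[1] + pads[1][0] + pads[1][1]
    dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, o)
    dcols = (dy_mat @ w.reshape(o, -1)).reshape(n, oh, ow, c, k, k)
    dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (n, c, k, k, oh, ow)
    dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
    h_span = (oh - 1) * stride + 1
    w_span = (ow - 1) * stride + 1
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h_span:stride, j:j + w_span:stride] += dcols[:, :, i, j]
    return dxp[:, :, pt:pt + in_hw[0], pl:pl + in_hw[1]]


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


class Layer:
    """Base layer; subclasses fill params/grads dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # non-trainable (running stats)

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def n_non_trainable(self) -> int:
        return sum(int(s.size) for s in self.state.values())


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 in_hw: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.in_hw = in_hw
        self.out_hw = (int(np.ceil(in_hw[0] / stride)), int(np.ceil(in_hw[1] / stride)))
        self.pads = (_same_pads(in_hw[0], self.out_hw[0], kernel, stride),
                     _same_pads(in_hw[1], self.out_hw[1], kernel, stride))
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.params["w"] = _glorot_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch, dtype=_DTYPE)

    def forward(self, x, training, rng):
        y, self._cols = _conv_fwd(x, self.params["w"], self.stride, self.pads)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        w = self.params["w"]
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        self.grads["w"] = _conv_bwd_weights(self._cols, dy, w.shape)
        return _conv_bwd_data(dy, w, self.stride, self.pads, self.in_hw)


class ConvTranspose2D(Layer):
    """Transposed convolution, 'same' padding: output spatial size = input * stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 in_hw: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.in_hw = in_hw
        self.out_hw = (in_hw[0] * stride, in_hw[1] * stride)
        # the virtual forward conv maps out_hw -> in_hw
        self.pads = (_same_pads(self.out_hw[0], in_hw[0], kernel, stride),
                     _same_pads(self.out_hw[1], in_hw[1], kernel, stride))
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        # stored in conv-weight layout of the virtual conv: (in_ch, out_ch, k, k)
        self.params["w"] = _glorot_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch, dtype=_DTYPE)

    def forward(self, x, training, rng):
        self._x = x
        y = _conv_bwd_data(x, self.params["w"], self.stride, self.pads, self.out_hw)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        w = self.params["w"]
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        dx, dy_cols = _conv_fwd(dy, w, self.stride, self.pads)
        self.grads["w"] = _conv_bwd_weights(dy_cols, self._x, w.shape)
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=_DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=_DTYPE)
        self.state["running_mean"] = np.zeros(channels, dtype=_DTYPE)
        self.state["running_var"] = np.ones(channels, dtype=_DTYPE)

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.state["running_mean"] = m * self.state["running_mean"] + (1 - m) * mean
            self.state["running_var"] = m * self.state["running_var"] + (1 - m) * var
        else:
            mean = self.state["running_mean"]
            var = self.state["running_var"]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        self._training = training
        g = self.params["gamma"]
        return g[None, :, None, None] * self._xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy):
        g = self.params["gamma"]
        self.grads["gamma"] = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * g[None, :, None, None]
        if not self._training:
            return dxhat * self._inv_std[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (self._inv_std[None, :, None, None] / n) * (
            n * dxhat - sum_dxhat - self._xhat * sum_dxhat_xhat
        )


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _glorot_uniform(rng, (in_features, out_features),
                                           in_features, out_features)
        self.params["b"] = np.zeros(out_features, dtype=_DTYPE)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(0)
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def n_trainable(self) -> int:
        return sum(layer.n_trainable() for layer in self.layers)

    def n_non_trainable(self) -> int:
        return sum(layer.n_non_trainable() for layer in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{**{k: v.copy() for k, v in l.params.items()},
                 **{k: v.copy() for k, v in l.state.items()}} for l in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights, strict=True):
            for k in layer.params:
                layer.params[k] = w[k].copy()
            for k in layer.state:
                layer.state[k] = w[k].copy()


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy computed from logits."""
    z, y = logits, targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def bce_with_logits_grad(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-logits))
    return (p - targets) / logits.size


class Adam:
    """Adam optimizer with the AMSGrad maximum-of-second-moment correction."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, amsgrad: bool = True):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.amsgrad = amsgrad
        self.t = 0
        self._slots = {}
        for layer, name in model.parameters():
            key = (id(layer), name)
            self._slots[key] = {
                "m": np.zeros_like(layer.params[name]),
                "v": np.zeros_like(layer.params[name]),
                "vhat": np.zeros_like(layer.params[name]),
            }

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for layer, name in self.model.parameters():
            g = layer.grads[name]
            s = self._slots[(id(layer), name)]
            s["m"] = b1 * s["m"] + (1 - b1) * g
            s["v"] = b2 * s["v"] + (1 - b2) * g * g
            if self.amsgrad:
                np.maximum(s["vhat"], s["v"], out=s["vhat"])
                v_use = s["vhat"]
            else:
                v_use = s["v"]
            layer.params[name] -= self.lr * (s["m"] / bias1) / (
                np.sqrt(v_use / bias2) + self.eps
            )
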