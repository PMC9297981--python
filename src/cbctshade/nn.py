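"""Minimal CPU neural-network engine for the U-Net translator.

No deep-learning framework is assumed: 2D convolutions are evaluated with an
im2col/matmul scheme, gradients are hand-derived, and Adam is implemented
directly.  The engine supports exactly what the shading-correction U-Net
needs: stride-1 'same' 3x3 convolutions, 2x2 max pooling, kernel-2/stride-2
transpose convolutions, batch normalization with freezable statistics,
dropout, ReLU/sigmoid, channel concatenation and an MAE loss.

Arrays are ``(batch, channels, height, width)`` float32 throughout.  Each
layer owns ``params``/``grads`` dicts and a ``trainable`` flag; frozen layers
receive no optimizer updates and frozen batch-norm layers also stop updating
their running statistics, so a frozen block is strictly inert.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "ConvTranspose2D", "BatchNorm2D", "Dropout",
    "MaxPool2D", "ReLU", "Sigmoid", "Adam", "mae_loss",
]


class Layer:
    """Base layer: parameter/grad storage plus a trainable flag."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) patch matrix for stride-1 convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(b, c * k * k, h * w)


class Conv2D(Layer):
    """Stride-1 'same'-padded 2D convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, seed: int = 0) -> None:
        super().__init__()
        if k % 2 == 0:
            raise ValueError("Conv2D supports odd kernels only ('same' padding)")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = np.random.default_rng(seed)
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.params["W"] = rng.normal(0, scale, (c_out, c_in * k * k)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        self._cache = (cols, x.shape)
        y = np.einsum("op,bpn->bon", self.params["W"], cols, optimize=True)
        y += self.params["b"][None, :, None]
        return y.reshape(b, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        b, c, h, w = xshape
        dy_flat = dy.reshape(b, self.c_out, h * w)
        self.grads["W"] = np.einsum("bon,bpn->op", dy_flat, cols, optimize=True)
        self.grads["b"] = dy_flat.sum(axis=(0, 2))
        # data gradient = transposed convolution of dy with W
        w4 = self.params["W"].reshape(self.c_out, self.c_in, self.k, self.k)
        w_flip = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, k, k)
        dy_cols = _im2col(dy, self.k, self.k // 2)
        dx = np.einsum(
            "cp,bpn->bcn", w_flip.reshape(self.c_in, self.c_out * self.k * self.k),
            dy_cols, optimize=True,
        )
        return dx.reshape(xshape)


class ConvTranspose2D(Layer):
    """Kernel-2, stride-2 transpose convolution (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, k: int = 2, seed: int = 0) -> None:
        super().__init__()
        if k != 2:
            raise NotImplementedError("only the kernel=stride=2 transpose conv is runnable")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = np.random.default_rng(seed)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = rng.normal(0, scale, (c_in, c_out, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        self._x = x
        y = np.einsum("bchw,coij->bohiwj", x, self.params["W"], optimize=True)
        y = y.reshape(b, self.c_out, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        b, c, h, w = x.shape
        dy6 = dy.reshape(b, self.c_out, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        # dy6: (B, O, H, W, 2, 2)
        self.grads["W"] = np.einsum("bchw,bohwij->coij", x, dy6, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        return np.einsum("bohwij,coij->bchw", dy6, self.params["W"], optimize=True)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with freezable running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        use_batch = training and self.trainable
        if use_batch:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, use_batch, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, use_batch, shape = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None] * inv[None, :, None, None]
        if not use_batch:
            return dy * g
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * self.params["gamma"][None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float = 0.1) -> None:
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        b, c, h, w = shape
        dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        return (
            dflat.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(shape)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -80.0, 80.0)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


class Adam:
    """Adam over the trainable layers of a network."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            if not layer.trainable:
                continue
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
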