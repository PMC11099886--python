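"""Minimal neural-network engine (numpy, explicit backprop).

Implements exactly the layer types the shift-estimation network and the
model-based recalibration need: per-column 1D convolutions with circular
padding on the defect axis, 2D convolutions (zero padding on the m/z axis,
circular on the defect axis), batch normalization, leaky rectification,
per-bin multilayer perceptrons with a bounded tanh output, a one-hidden-
layer MLP for scalar function approximation, and an Adam optimizer.

Layout convention: the network input is ``(N, 1, K, L)`` (batch, channel,
m/z column, defect row).  Internally the per-column blocks run
column-major ``(K, N, L, C)`` and the 2D block runs ``(N, K, L, C)``
(channels last), so that every convolution is one batched BLAS matrix
product and data is transposed only at block boundaries — on a single
CPU the elementwise traffic, not the arithmetic, is the cost that matters.
Forward passes cache what the matching ``backward`` needs; ``backward``
accumulates parameter gradients and returns the input gradient.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "", dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ToColumns(Layer):
    """(N, 1, K, L) histogram batch -> column-major (K, N, L, 1)."""

    def forward(self, x, training):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, K, L)")
        return np.ascontiguousarray(x[:, 0].transpose(1, 0, 2))[..., None]

    def backward(self, gy):
        return np.ascontiguousarray(gy[..., 0].transpose(1, 0, 2))[:, None, :, :]


class ColumnsToImage(Layer):
    """(K, N, L, C) -> (N, K, L, C) at the 1D/2D block boundary."""

    def forward(self, x, training):
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3))

    def backward(self, gy):
        return np.ascontiguousarray(gy.transpose(1, 0, 2, 3))


class ImageToColumns(Layer):
    """(N, K, L, C) -> (K, N, L, C)."""

    def forward(self, x, training):
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3))

    def backward(self, gy):
        return np.ascontiguousarray(gy.transpose(1, 0, 2, 3))


def _circular_windows(t: np.ndarray, kernel: int) -> np.ndarray:
    """(K, N, L, C) -> contiguous (K, N*L, kernel*C) of circular L-windows."""
    K, N, L, C = t.shape
    pad = kernel // 2
    if pad:
        tp = np.concatenate([t[:, :, L - pad :, :], t, t[:, :, :pad, :]], axis=2)
    else:
        tp = t
    A = np.empty((K, N, L, kernel, C), dtype=t.dtype)
    for i in range(kernel):
        A[:, :, :, i, :] = tp[:, :, i : i + L, :]
    return A.reshape(K, N * L, kernel * C)


class ColumnConv1d(Layer):
    """1D convolution along the defect axis with an independent filter bank
    per m/z column and circular padding (the defect axis wraps).

    Operates column-major: input (K, N, L, C_in), output (K, N, L, C_out).
    One batched matrix product: windows (K, N*L, kernel*C) x weights
    (K, kernel*C, C_out).
    """

    def __init__(self, n_columns: int, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32, bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (c_in * kernel))
        # weight layout (K, kernel, C_in, C_out) to match the gathered windows
        self.W = Parameter(rng.normal(0.0, scale, size=(n_columns, kernel, c_in, c_out)),
                           dtype=dtype)
        self.b = Parameter(np.zeros((n_columns, c_out)), dtype=dtype) if bias else None
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training):
        K, N, L, C = x.shape
        if self.kernel > L:
            raise ValueError("kernel larger than the defect axis")
        A = _circular_windows(x, self.kernel)  # (K, N*L, kernel*C)
        Wm = self.W.value.reshape(K, self.kernel * C, self.c_out)
        y = A @ Wm
        if self.b is not None:
            y += self.b.value[:, None, :]
        self._cache = (A, (K, N, L, C))
        return y.reshape(K, N, L, self.c_out)

    def backward(self, gy):
        A, (K, N, L, C) = self._cache
        G = gy.reshape(K, N * L, self.c_out)
        gW = A.transpose(0, 2, 1) @ G  # (K, kernel*C, c_out)
        self.W.grad += gW.reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += G.sum(axis=1)
        # input gradient = circular correlation with the flipped kernel:
        # dx[m] = sum_i W[kernel-1-i] gy[(m + i - pad) % L]
        Gw = _circular_windows(gy, self.kernel)  # (K, N*L, kernel*c_out)
        Wb = self.W.value[:, ::-1, :, :].transpose(0, 1, 3, 2)  # (K, kernel, c_out, C)
        gx = Gw @ np.ascontiguousarray(Wb).reshape(K, self.kernel * self.c_out, C)
        return gx.reshape(K, N, L, C)


class Conv2d(Layer):
    """2D convolution, channels last: input (N, K, L, C_in) -> (N, K, L, C_out).

    Zero padding on the m/z (K) axis, circular padding on the defect (L)
    axis.  Direct accumulation: one channel-mixing matrix product per
    kernel offset.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32, bias: bool = True):
        kh, kw = kernel
        if kh % 2 != 1 or kw % 2 != 1:
            raise ValueError("kernel sizes must be odd")
        scale = np.sqrt(2.0 / (c_in * kh * kw))
        # weight layout (kh, kw, C_in, C_out)
        self.W = Parameter(rng.normal(0.0, scale, size=(kh, kw, c_in, c_out)), dtype=dtype)
        self.b = Parameter(np.zeros(c_out), dtype=dtype) if bias else None
        self.kh, self.kw = kh, kw
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def _pad(self, xt):
        pk, pl = self.kh // 2, self.kw // 2
        N, K, L, C = xt.shape
        out = np.zeros((N, K + 2 * pk, L + 2 * pl, C), dtype=xt.dtype)
        out[:, pk : pk + K, pl : pl + L, :] = xt
        if pl:
            out[:, pk : pk + K, :pl, :] = xt[:, :, L - pl :, :]
            out[:, pk : pk + K, pl + L :, :] = xt[:, :, :pl, :]
        return out

    def forward(self, x, training):
        kh, kw = self.kh, self.kw
        N, K, L, C = x.shape
        xtp = self._pad(x)
        y = np.zeros((N, K, L, self.c_out), dtype=x.dtype)
        W = self.W.value
        for a in range(kh):
            for b in range(kw):
                patch = xtp[:, a : a + K, b : b + L, :].reshape(N * K * L, C)
                y += (patch @ W[a, b]).reshape(N, K, L, self.c_out)
        if self.b is not None:
            y += self.b.value
        self._cache = (xtp, x.shape)
        return y

    def backward(self, gy):
        xtp, xshape = self._cache
        kh, kw = self.kh, self.kw
        pk, pl = kh // 2, kw // 2
        N, K, L, C = xshape
        Gm = gy.reshape(N, K * L, self.c_out)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 1, 2))
        W = self.W.value
        gxp = np.zeros_like(xtp)
        for a in range(kh):
            for b in range(kw):
                patch = xtp[:, a : a + K, b : b + L, :].reshape(N * K * L, C)
                self.W.grad[a, b] += patch.T @ Gm.reshape(N * K * L, self.c_out)
                gxp[:, a : a + K, b : b + L, :] += (Gm @ W[a, b].T).reshape(N, K, L, C)
        gx = gxp[:, pk : pk + K, pl : pl + L, :].copy()
        if pl:
            gx[:, :, L - pl :, :] += gxp[:, pk : pk + K, :pl, :]
            gx[:, :, :pl, :] += gxp[:, pk : pk + K, pl + L :, :]
        return gx


class BatchNorm(Layer):
    """Batch normalization for either block layout.

    ``layout="columns"``: input (K, N, L, C), statistics and affine
    parameters per (column, channel) — the per-column 1D block keeps
    columns independent.  ``layout="channels"``: input (N, K, L, C),
    statistics per channel (plain 2D batch norm).
    """

    def __init__(self, c: int, n_columns: int | None = None, layout: str = "channels",
                 momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        if layout not in ("columns", "channels"):
            raise ValueError(f"unknown layout {layout!r}")
        if layout == "columns" and n_columns is None:
            raise ValueError("columns layout needs n_columns")
        shape = (n_columns, 1, 1, c) if layout == "columns" else (c,)
        self.layout = layout
        self.axes = (1, 2) if layout == "columns" else (0, 1, 2)
        self.gamma = Parameter(np.ones(shape), dtype=dtype)
        self.beta = Parameter(np.zeros(shape), dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(shape, dtype=dtype)
        self.running_var = np.ones(shape, dtype=dtype)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        kd = self.layout == "columns"
        if training:
            mean = x.mean(axis=self.axes, keepdims=kd)
            var = np.square(x).mean(axis=self.axes, keepdims=kd) - np.square(mean)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        y = xhat * self.gamma.value + self.beta.value
        self._cache = (xhat, inv_std, training)
        return y

    def backward(self, gy):
        xhat, inv_std, training = self._cache
        kd = self.layout == "columns"
        gy_xhat = gy * xhat
        self.gamma.grad += gy_xhat.sum(axis=self.axes, keepdims=kd).reshape(
            self.gamma.value.shape)
        self.beta.grad += gy.sum(axis=self.axes, keepdims=kd).reshape(self.beta.value.shape)
        g = self.gamma.value * inv_std
        if not training:
            return gy * g
        mean_gy = gy.mean(axis=self.axes, keepdims=kd)
        mean_gy_xhat = gy_xhat.mean(axis=self.axes, keepdims=kd)
        return g * (gy - mean_gy - xhat * mean_gy_xhat)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._y = None

    def forward(self, x, training):
        # max(x, slope*x) == leaky rectification for 0 < slope < 1
        y = np.maximum(x, self.slope * x)
        self._y = y
        return y

    def backward(self, gy):
        return np.where(self._y >= 0, gy, self.slope * gy)


class PerBinMLP(Layer):
    """Independent two-layer perceptron per m/z column, tanh/2 output.

    Input column-major (K, N, L, 1); output (N, K) bounded to [-0.5, 0.5].
    """

    def __init__(self, n_columns: int, l_in: int, hidden: int, rng: np.random.Generator,
                 slope: float = 0.01, dtype=np.float32):
        self.W1 = Parameter(rng.normal(0.0, np.sqrt(2.0 / l_in), size=(n_columns, l_in, hidden)),
                            dtype=dtype)
        self.b1 = Parameter(np.zeros((n_columns, 1, hidden)), dtype=dtype)
        self.W2 = Parameter(rng.normal(0.0, np.sqrt(1.0 / hidden), size=(n_columns, hidden)),
                            dtype=dtype)
        self.b2 = Parameter(np.zeros(n_columns), dtype=dtype)
        self.slope = slope
        self._cache = None

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, training):
        if x.ndim != 4 or x.shape[3] != 1:
            raise ValueError("PerBinMLP expects (K, N, L, 1) input")
        xs = x[..., 0]  # (K, N, L)
        pre = xs @ self.W1.value + self.b1.value  # (K, N, H)
        h = np.maximum(pre, self.slope * pre)
        out = np.einsum("knh,kh->kn", h, self.W2.value) + self.b2.value[:, None]
        t = np.tanh(out)
        self._cache = (xs, h, t)
        return 0.5 * t.T  # (N, K)

    def backward(self, gy):
        xs, h, t = self._cache
        dout = gy.T * 0.5 * (1.0 - t**2)  # (K, N)
        self.b2.grad += dout.sum(axis=1)
        self.W2.grad += np.einsum("kn,knh->kh", dout, h)
        dh = dout[:, :, None] * self.W2.value[:, None, :]
        dpre = np.where(h >= 0, dh, self.slope * dh)
        self.b1.grad += dpre.sum(axis=1, keepdims=True)
        self.W1.grad += xs.transpose(0, 2, 1) @ dpre  # (K, L, H)
        gx = dpre @ self.W1.value.transpose(0, 2, 1)  # (K, N, L)
        return gx[..., None]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam optimizer on a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class TinyMLP:
    """One-hidden-layer feed-forward map from a scalar input, ReLU hidden units.

    Used to parametrize smooth functions of m/z (mass shift, baseline) in the
    model-based recalibration.  ``forward`` evaluates the raw (unsquashed)
    output on a batch of scaled inputs; ``backward`` takes d(loss)/d(output)
    and accumulates parameter gradients.
    """

    def __init__(self, hidden: int, rng: np.random.Generator, out_scale: float = 1.0):
        self.W1 = Parameter(rng.normal(0.0, 1.0, size=(hidden,)))
        self.b1 = Parameter(rng.uniform(-1.0, 0.0, size=(hidden,)))
        self.W2 = Parameter(rng.normal(0.0, out_scale / np.sqrt(hidden), size=(hidden,)))
        self.b2 = Parameter(np.zeros(1))
        self._cache = None

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        pre = x[:, None] * self.W1.value[None, :] + self.b1.value[None, :]
        h = np.maximum(pre, 0.0)
        out = h @ self.W2.value + self.b2.value[0]
        self._cache = (x, pre >= 0, h)
        return out

    def backward(self, gout: np.ndarray) -> None:
        x, mask, h = self._cache
        self.b2.grad[0] += gout.sum()
        self.W2.grad += gout @ h
        dh = gout[:, None] * self.W2.value[None, :]
        dpre = np.where(mask, dh, 0.0)
        self.b1.grad += dpre.sum(axis=0)
        self.W1.grad += dpre.T @ x

    def state(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.value, "b1": self.b1.value, "W2": self.W2.value, "b2": self.b2.value}


def numerical_gradient(f, param: Parameter, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar ``f()`` w.r.t. one parameter."""
    g = np.zeros_like(param.value)
    flat = param.value.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        gflat[i] = (fp - fm) / (2 * eps)
    return g
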