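"""Minimal 1-D convolutional network stack with explicit forward/backward.

The attribution stage needs direct access to every layer's weights and
cached activations (layer-wise relevance propagation redistributes through
the explicit weighted connections), so the network is built from small
layer objects that expose exactly that.  Shapes follow the convention
(batch, time, channels) for convolutional layers and (batch, features) for
dense layers.

Gradients accumulate into per-layer ``g*`` buffers; :class:`Adam` updates
the referenced arrays in place.
"""

from __future__ import annotations

import numpy as np


def _sign_safe(z: np.ndarray) -> np.ndarray:
    """sign(z) with sign(0) := 1, so an epsilon stabilizer never vanishes."""
    s = np.sign(z)
    s[s == 0.0] = 1.0
    return s


def same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(pad_left, pad_total, out_length) for 'same'-style padding."""
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total, out


class Layer:
    """Base class: parameters as (value, grad) pairs, optional state dict."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, val in state.items():
            getattr(self, key)[...] = val

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None, bias: bool = True,
                 dtype=np.float64) -> None:
        scale = np.sqrt(2.0 / n_in) if scale is None else scale
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.gW = np.zeros_like(self.W)
        self.use_bias = bias
        self.b = np.zeros(n_out, dtype=dtype)
        self.gb = np.zeros_like(self.b)
        self.x: np.ndarray | None = None
        self.z: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        self.z = x @ self.W + (self.b if self.use_bias else 0.0)
        return self.z

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gW += self.x.T @ gy
        if self.use_bias:
            self.gb += gy.sum(axis=0)
        return gy @ self.W.T

    def params(self):
        return [(self.W, self.gW)] + ([(self.b, self.gb)] if self.use_bias else [])

    def state(self):
        return {"W": self.W, "b": self.b}

    def lrp(self, R: np.ndarray, eps: float) -> np.ndarray:
        """Epsilon-rule redistribution through the weighted connections.

        Bias relevance is absorbed: the denominator is the full
        pre-activation while only the x_i * w_ij contributions are
        redistributed to the inputs.
        """
        z = self.z
        if eps == 0.0 and np.any(z == 0.0):
            raise ZeroDivisionError(
                "zero pre-activation with eps=0; use a positive epsilon stabilizer"
            )
        factor = R / (z + eps * _sign_safe(z))
        return self.x * (factor @ self.W.T)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0.0
        return np.where(self.mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self.mask, gy, 0.0)

    def lrp(self, R: np.ndarray, eps: float) -> np.ndarray:
        # Relevance flows unchanged through the nonlinearity; redistribution
        # happens at the weighted layers, whose cached inputs are already
        # post-activation values.
        return R


class Conv1d(Layer):
    """1-D convolution, zero 'same' padding, arbitrary stride.

    Weights are stored as (kernel * in_ch, out_ch), row index kk*C + c, so
    the convolution is a dense product against im2col patches — the exact
    "equivalent sparse dense connections" view the relevance rule uses.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=np.float64) -> None:
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.W = (rng.standard_normal((kernel * in_ch, out_ch)) * scale).astype(dtype)
        self.gW = np.zeros_like(self.W)
        self.use_bias = bias
        self.b = np.zeros(out_ch, dtype=dtype)
        self.gb = np.zeros_like(self.b)

    def _geometry(self, T: int) -> tuple[int, int, int]:
        return same_pad(T, self.kernel, self.stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        pl, total, out = self._geometry(T)
        xp = np.zeros((B, T + total, C), dtype=x.dtype)
        xp[:, pl : pl + T] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (B, out_full, C, k) -> strided -> (B, out, k, C) -> (B, out, k*C)
        cols = win[:, :: self.stride].transpose(0, 1, 3, 2)
        self.cols = np.ascontiguousarray(cols).reshape(B, out, -1)
        self.T_in = T
        self.z = self.cols @ self.W + (self.b if self.use_bias else 0.0)
        return self.z

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, out, F = gy.shape
        k, s, C = self.kernel, self.stride, self.in_ch
        self.gW += self.cols.reshape(-1, k * C).T @ gy.reshape(-1, F)
        if self.use_bias:
            self.gb += gy.sum(axis=(0, 1))
        gcols = (gy @ self.W.T).reshape(B, out, k, C)
        return self._scatter(gcols)

    def _scatter(self, gcols: np.ndarray) -> np.ndarray:
        """col2im: accumulate patch-space values back onto the input rows."""
        B, out, k, C = gcols.shape
        T = self.T_in
        pl, total, _ = self._geometry(T)
        gxp = np.zeros((B, T + total, C), dtype=gcols.dtype)
        base = np.arange(out) * self.stride
        for kk in range(k):
            gxp[:, base + kk] += gcols[:, :, kk, :]
        return gxp[:, pl : pl + T]

    def params(self):
        return [(self.W, self.gW)] + ([(self.b, self.gb)] if self.use_bias else [])

    def state(self):
        return {"W": self.W, "b": self.b}

    def lrp(self, R: np.ndarray, eps: float) -> np.ndarray:
        z = self.z
        if eps == 0.0 and np.any(z == 0.0):
            raise ZeroDivisionError(
                "zero pre-activation with eps=0; use a positive epsilon stabilizer"
            )
        factor = R / (z + eps * _sign_safe(z))  # (B, out, F)
        contrib = self.cols * (factor @ self.W.T)  # (B, out, k*C)
        B, out, _ = contrib.shape
        return self._scatter(contrib.reshape(B, out, self.kernel, self.in_ch))


class ConvTranspose1d(Layer):
    """Adjoint-geometry transposed convolution mapping L_in -> L_out rows.

    The forward pass is exactly the adjoint of a stride-``stride`` 'same'
    convolution that maps L_out -> L_in rows, so decoder stages invert the
    encoder's length arithmetic without ad-hoc output padding.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 L_in: int, L_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64) -> None:
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.L_in, self.L_out = L_in, L_out
        pl, total, out = same_pad(L_out, kernel, stride)
        if out != L_in:
            raise ValueError(
                f"geometry mismatch: conv({L_out}) gives {out} rows, expected {L_in}"
            )
        self.pl, self.total = pl, total
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.W = (rng.standard_normal((kernel * out_ch, in_ch)) * scale).astype(dtype)
        self.gW = np.zeros_like(self.W)
        self.use_bias = bias
        self.b = np.zeros(out_ch, dtype=dtype)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        B = x.shape[0]
        k, s = self.kernel, self.stride
        cols = (x @ self.W.T).reshape(B, self.L_in, k, self.out_ch)
        yp = np.zeros((B, self.L_out + self.total, self.out_ch), dtype=x.dtype)
        base = np.arange(self.L_in) * s
        for kk in range(k):
            yp[:, base + kk] += cols[:, :, kk, :]
        y = yp[:, self.pl : self.pl + self.L_out]
        if self.use_bias:
            y = y + self.b
        return y

    def _gather(self, gy: np.ndarray) -> np.ndarray:
        """im2col of the (padded) output-side array: (B, L_in, k*out_ch)."""
        B = gy.shape[0]
        gyp = np.zeros((B, self.L_out + self.total, self.out_ch), dtype=gy.dtype)
        gyp[:, self.pl : self.pl + self.L_out] = gy
        win = np.lib.stride_tricks.sliding_window_view(gyp, self.kernel, axis=1)
        cols = win[:, :: self.stride].transpose(0, 1, 3, 2)
        return np.ascontiguousarray(cols).reshape(B, self.L_in, -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gcols = self._gather(gy)
        B = gy.shape[0]
        self.gW += gcols.reshape(-1, self.kernel * self.out_ch).T @ self.x.reshape(
            -1, self.in_ch
        )
        if self.use_bias:
            self.gb += gy.sum(axis=(0, 1))
        return gcols @ self.W

    def params(self):
        return [(self.W, self.gW)] + ([(self.b, self.gb)] if self.use_bias else [])

    def state(self):
        return {"W": self.W, "b": self.b}


class L2Normalize(Layer):
    """Scale each sample of a (B, D) batch to unit Euclidean norm."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.norm = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(self.norm == 0.0):
            raise ZeroDivisionError("cannot normalize a zero vector")
        self.y = x / self.norm
        return self.y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        inner = (self.y * gy).sum(axis=1, keepdims=True)
        return (gy - self.y * inner) / self.norm


class BlockL2Normalize(Layer):
    """Scale each sample of a (B, T, C) batch to unit Frobenius norm."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.norm = np.sqrt((x * x).sum(axis=(1, 2), keepdims=True))
        if np.any(self.norm == 0.0):
            raise ZeroDivisionError("cannot normalize a zero block")
        self.y = x / self.norm
        return self.y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        inner = (self.y * gy).sum(axis=(1, 2), keepdims=True)
        return (gy - self.y * inner) / self.norm


class Adam:
    """Adaptive-moment gradient descent over (value, grad) array pairs."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for v, _ in params]
        self.v = [np.zeros_like(v) for v, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for (val, grad), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * grad
            v *= b2
            v += (1.0 - b2) * grad * grad
            val -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for _, grad in self.params:
            grad[...] = 0.0
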