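"""Minimal trainable 3D layers on NumPy.

Implements exactly the layer set the volumetric U-net needs — 3D
convolution (stride 1 and 2), transposed convolution (kernel 2, stride 2),
group normalization and channel-wise PReLU — with hand-written backward
passes.  Activations are kept channel-last ``(B, D, H, W, C)`` so every
convolution reduces to a small number of BLAS GEMMs over shifted views of
the padded input ("shift-and-GEMM"), which is the fastest arrangement for
the narrow channel counts used here.

Correctness of every backward pass is pinned by numerical finite-difference
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "ConvTranspose3d", "GroupNorm", "PReLU", "SGD", "global_grad_norm"]


class Layer:
    """Base class: parameters and matching gradient buffers by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _offsets(kernel: int):
    rng = range(kernel)
    return [(a, b, c) for a in rng for b in rng for c in rng]


class Conv3d(Layer):
    """3D convolution, kernel k, stride 1 or 2, 'same'-style padding k//2.

    Weight shape ``(k, k, k, C_in, C_out)``.  For even input sizes and
    stride 2 the output is exactly half the input size.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        fan_in = kernel**3 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, kernel, c_in, c_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.zero_grad()
        self._cache = None

    def _out_size(self, n: int) -> int:
        return (n + 2 * self.pad - self.kernel) // self.stride + 1

    def _row_window(self, padded: np.ndarray, a: int, out_dims) -> np.ndarray:
        """Sliding (kernel, kernel, C_in) window over (y, x) for z-offset a:
        shape (B, Do, Ho, Wo, k, k, C_in), a zero-copy strided view."""
        do, ho, wo = out_dims
        k, s = self.kernel, self.stride
        B = padded.shape[0]
        sb, sz, sy, sx, sc = padded.strides
        return np.lib.stride_tricks.as_strided(
            padded[:, a:],
            shape=(B, do, ho, wo, k, k, self.c_in),
            strides=(sb, s * sz, s * sy, s * sx, sy, sx, sc),
            writeable=False,
        )

    def _w_mat(self) -> np.ndarray:
        # (k_z, k_y * k_x * C_in, C_out) view of the weights
        k = self.kernel
        return self.params["W"].reshape(k, k * k * self.c_in, self.c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, D, H, W, _ = x.shape
        p, k = self.pad, self.kernel
        padded = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        out_dims = (self._out_size(D), self._out_size(H), self._out_size(W))
        wmat = self._w_mat()
        kk = k * k * self.c_in
        y = np.empty((B, *out_dims, self.c_out), dtype=x.dtype)
        y[...] = self.params["b"]
        yf = y.reshape(-1, self.c_out)
        for a in range(k):
            win = self._row_window(padded, a, out_dims)
            yf += win.reshape(-1, kk) @ wmat[a]
        self._cache = (padded, x.shape, out_dims)
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        padded, x_shape, out_dims = self._cache
        p, s, k = self.pad, self.stride, self.kernel
        B = gout.shape[0]
        do, ho, wo = out_dims
        gf = gout.reshape(-1, self.c_out)
        wmat = self._w_mat()
        gw = self.grads["W"].reshape(k, k * k * self.c_in, self.c_out)
        kk = k * k * self.c_in
        self.grads["b"] += gout.sum(axis=(0, 1, 2, 3))
        gpad = np.zeros_like(padded)
        w_flat = self.params["W"].reshape(k, k, k, self.c_in, self.c_out)
        for a in range(k):
            win = self._row_window(padded, a, out_dims)
            gw[a] += win.reshape(-1, kk).T @ gf
            # input gradient per (b, c) offset: small GEMMs, no 9x buffer
            for b in range(k):
                for c in range(k):
                    gin = (gf @ w_flat[a, b, c].T).reshape(B, do, ho, wo, self.c_in)
                    gpad[:, a : a + s * (do - 1) + 1 : s, b : b + s * (ho - 1) + 1 : s,
                         c : c + s * (wo - 1) + 1 : s, :] += gin
        self._cache = None
        if p:
            return gpad[:, p : p + x_shape[1], p : p + x_shape[2], p : p + x_shape[3], :]
        return gpad


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    Each output voxel receives exactly one kernel tap, which avoids
    checkerboard artifacts and keeps the backward pass trivial.
    Weight shape ``(2, 2, 2, C_in, C_out)``.
    """

    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(2, 2, 2, c_in, c_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, D, H, W, _ = x.shape
        Wm = self.params["W"]
        xf = x.reshape(-1, self.c_in)
        y = np.empty((B, 2 * D, 2 * H, 2 * W, self.c_out), dtype=x.dtype)
        for a, b, c in _offsets(2):
            y[:, a::2, b::2, c::2, :] = (xf @ Wm[a, b, c]).reshape(B, D, H, W, self.c_out)
        y += self.params["b"]
        self._cache = x
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        xf = x.reshape(-1, self.c_in)
        Wm = self.params["W"]
        self.grads["b"] += gout.sum(axis=(0, 1, 2, 3))
        gx = np.zeros_like(xf)
        for a, b, c in _offsets(2):
            gf = np.ascontiguousarray(gout[:, a::2, b::2, c::2, :]).reshape(-1, self.c_out)
            self.grads["W"][a, b, c] += xf.T @ gf
            gx += gf @ Wm[a, b, c].T
        self._cache = None
        return gx.reshape(x.shape)


class GroupNorm(Layer):
    """Group normalization over (spatial, channels-within-group) per sample.

    Statistics never mix samples, so the forward pass is independent of
    batch composition and identical in train and eval mode.
    """

    def __init__(self, channels: int, groups: int, eps: float = 1e-5, *, dtype=np.float32):
        super().__init__()
        if channels % groups != 0:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.params = {"gamma": np.ones(channels, dtype=dtype), "beta": np.zeros(channels, dtype=dtype)}
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        C = self.channels
        g = self.groups
        xg = x.reshape(B, -1, g, C // g)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mu) * inv
        y = xhat.reshape(x.shape) * self.params["gamma"] + self.params["beta"]
        self._cache = (xhat, inv, x.shape)
        return y.astype(x.dtype)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, x_shape = self._cache
        B = x_shape[0]
        C = self.channels
        g = self.groups
        xhat_full = xhat.reshape(x_shape)
        self.grads["gamma"] += (gout * xhat_full).sum(axis=(0, 1, 2, 3))
        self.grads["beta"] += gout.sum(axis=(0, 1, 2, 3))
        dxhat = (gout * self.params["gamma"]).reshape(B, -1, g, C // g)
        m1 = dxhat.mean(axis=(1, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 3), keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        self._cache = None
        return dx.reshape(x_shape).astype(gout.dtype)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative slope per channel."""

    def __init__(self, channels: int, init_slope: float = 0.25, *, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.params = {"alpha": np.full(channels, init_slope, dtype=dtype)}
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        neg = x < 0
        y = np.where(neg, x * self.params["alpha"], x)
        self._cache = (x, neg)
        return y.astype(x.dtype)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, neg = self._cache
        self.grads["alpha"] += (gout * x * neg).sum(axis=(0, 1, 2, 3))
        dx = np.where(neg, gout * self.params["alpha"], gout)
        self._cache = None
        return dx.astype(gout.dtype)


def global_grad_norm(layers) -> float:
    """L2 norm over all gradient entries of all layers."""
    total = 0.0
    for layer in layers:
        for grad in layer.grads.values():
            total += float(np.sum(np.square(grad, dtype=np.float64)))
    return float(np.sqrt(total))


class SGD:
    """Stochastic gradient descent with optional momentum and global-norm
    gradient clipping."""

    def __init__(self, layers, lr: float, momentum: float = 0.0, clip_norm: float | None = None):
        self.layers = list(layers)
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in self.layers
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            norm = global_grad_norm(self.layers)
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
        for layer, vel in zip(self.layers, self._velocity):
            for k, p in layer.params.items():
                g = layer.grads[k] * scale
                if self.momentum > 0:
                    vel[k] = self.momentum * vel[k] + g
                    g = vel[k]
                p -= (self.lr * g).astype(p.dtype)
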