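"""Small group-normalized residual CNNs with exact per-sample gradients.

Implemented directly on NumPy arrays with hand-written batched backprop.  The
design constraint that shapes everything here is DP-SGD's need for *exact
per-sample gradients*: no layer may couple samples (hence group normalization,
never batch normalization), and the backward pass keeps the batch axis on
every parameter gradient, so clipping can act on each record's full flattened
gradient before aggregation.

The architecture family is the compact "ResNet9" used for fast image
classification: stem convolution, three downsampling stages, a residual block
after the first and last stage, global average pooling and a linear head.  It
generalizes to 3D volumes by swapping 3x3 kernels for 3x3x3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = ["ModelConfig", "build_model", "Network"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description.

    ``widths`` are the channel counts of stem and the three stages; group
    normalization uses ``groups`` channel groups, falling back to
    gcd(groups, channels) where the width is not divisible.  ``activation``
    is "relu" or "mish" (the smoother choice favoured for private training).
    """

    ndim: int = 2
    widths: tuple[int, int, int, int] = (8, 16, 32, 32)
    groups: int = 32
    activation: str = "mish"
    n_outputs: int = 1
    in_channels: int = 1
    dtype: str = "float32"  # float64 available for bit-level comparisons
    stem_pool: bool = False  # extra 2x pool after the stem for larger inputs

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if len(self.widths) != 4 or any(w < 1 for w in self.widths):
            raise ValueError("widths must be four positive channel counts")
        if self.activation not in ("relu", "mish"):
            raise ValueError("activation must be 'relu' or 'mish'")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if self.groups < 1:
            raise ValueError("groups must be >= 1")


# --------------------------------------------------------------------------
# layers


class Layer:
    """Batched layer: forward caches what backward needs; backward returns
    the input gradient and stashes per-sample parameter gradients."""

    def params(self) -> list[np.ndarray]:
        return []

    def per_sample_grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _kernel_offsets(k: int, ndim: int):
    """All k^ndim kernel offset index tuples."""
    grids = np.meshgrid(*([np.arange(k)] * ndim), indexing="ij")
    return list(zip(*[g.ravel() for g in grids]))


def _pad_same(x: np.ndarray, k: int, ndim: int) -> np.ndarray:
    pad = k // 2
    return np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * ndim)


class Conv(Layer):
    """Stride-1 'same' convolution with odd kernel (default 3^ndim).

    Evaluated as one batched GEMM per sample on an offset-major column buffer
    (im2col with layout (B, K·C, L)); the buffer is filled by row-contiguous
    copies of shifted views of the padded input, which keeps the copies fast
    and the GEMM inner dimension large.
    """

    def __init__(self, cin: int, cout: int, ndim: int, rng: np.random.Generator,
                 k: int = 3, dtype: str = "float32"):
        self.cin, self.cout, self.ndim, self.k = cin, cout, ndim, k
        fan_in = cin * k**ndim
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(cout, cin) + (k,) * ndim).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self._cols: np.ndarray | None = None
        self._spatial: tuple[int, ...] = ()
        self.dW_ps: np.ndarray | None = None
        self.db_ps: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def per_sample_grads(self) -> list[np.ndarray]:
        return [self.dW_ps, self.db_ps]

    @staticmethod
    def _im2col(x: np.ndarray, k: int, ndim: int) -> np.ndarray:
        """Offset-major column buffer (B, K·C, L)."""
        b, cin = x.shape[:2]
        spatial = x.shape[2:]
        L = int(np.prod(spatial))
        offsets = _kernel_offsets(k, ndim)
        xp = _pad_same(x, k, ndim)
        cols = np.empty((b, len(offsets) * cin, L), dtype=x.dtype)
        for i, offset in enumerate(offsets):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(offset, spatial)
            )
            cols[:, i * cin: (i + 1) * cin, :] = xp[sl].reshape(b, cin, L)
        return cols

    def _weight_matrix(self, W: np.ndarray) -> np.ndarray:
        """(cout, K·cin) in the same offset-major layout as the columns."""
        axes = (0,) + tuple(range(2, 2 + self.ndim)) + (1,)
        return np.ascontiguousarray(W.transpose(axes)).reshape(W.shape[0], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2:]
        b = x.shape[0]
        cols = self._im2col(x, self.k, self.ndim)
        y = self._weight_matrix(self.W) @ cols  # (B, cout, L)
        y += self.b[None, :, None]
        self._cols = cols
        return y.reshape((b, self.cout) + self._spatial)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = dy.shape[0]
        spatial = self._spatial
        dyf = np.ascontiguousarray(dy.reshape(b, self.cout, -1))
        # per-sample weight gradient in offset-major layout, then restore
        dw_flat = dyf @ self._cols.transpose(0, 2, 1)  # (B, cout, K*cin)
        koff = len(_kernel_offsets(self.k, self.ndim))
        dw = dw_flat.reshape((b, self.cout) + (self.k,) * self.ndim + (self.cin,))
        axes = (0, 1, 2 + self.ndim) + tuple(range(2, 2 + self.ndim))
        self.dW_ps = dw.transpose(axes)
        self.db_ps = dyf.sum(axis=2)
        # dX = dy (*) flipped, channel-transposed kernel
        flip = self.W[(slice(None), slice(None)) + (slice(None, None, -1),) * self.ndim]
        Wt = np.swapaxes(flip, 0, 1)  # (cin, cout, *k)
        tmp_axes = (0,) + tuple(range(2, 2 + self.ndim)) + (1,)
        Wt_mat = np.ascontiguousarray(Wt.transpose(tmp_axes)).reshape(self.cin, -1)
        dcols = self._im2col(dy, self.k, self.ndim)
        dx = (Wt_mat @ dcols).reshape((b, self.cin) + spatial)
        self._cols = None
        return dx


class GroupNorm(Layer):
    """Per-sample, per-group feature normalization with channel affine."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5,
                 dtype: str = "float32"):
        g = math.gcd(groups, channels)
        self.channels, self.groups, self.eps = channels, g, eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma_ps: np.ndarray | None = None
        self.dbeta_ps: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def per_sample_grads(self) -> list[np.ndarray]:
        return [self.dgamma_ps, self.dbeta_ps]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c = x.shape[:2]
        self._shape = x.shape
        xg = x.reshape(b, self.groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (xg - mu) * self._inv
        xhat = self._xhat.reshape(x.shape)
        shape = (1, c) + (1,) * (x.ndim - 2)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c = dy.shape[:2]
        spatial_axes = tuple(range(2, dy.ndim))
        xhat_full = self._xhat.reshape(self._shape)
        self.dgamma_ps = (dy * xhat_full).sum(axis=spatial_axes)
        self.dbeta_ps = dy.sum(axis=spatial_axes)
        shape = (1, c) + (1,) * (dy.ndim - 2)
        dxhat = (dy * self.gamma.reshape(shape)).reshape(b, self.groups, -1)
        m = dxhat.shape[2]
        dx = (
            dxhat
            - dxhat.mean(axis=2, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=2, keepdims=True)
        ) * self._inv
        return dx.reshape(self._shape)


class Activation(Layer):
    def __init__(self, kind: str):
        self.kind = kind

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        sp = np.logaddexp(0.0, x)  # softplus
        self._tanh_sp = np.tanh(sp)
        return x * self._tanh_sp

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        if self.kind == "relu":
            return dy * (x > 0)
        t = self._tanh_sp
        sig = expit(x)
        return dy * (t + x * (1.0 - t**2) * sig)


class MaxPool(Layer):
    """Non-overlapping 2^ndim max pooling; spatial extents must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        ndim = x.ndim - 2
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"MaxPool needs even spatial extents, got {x.shape[2:]}")
        shape = x.shape[:2]
        for s in x.shape[2:]:
            shape += (s // 2, 2)
        xr = x.reshape(shape)
        axes = tuple(3 + 2 * i for i in range(ndim))
        y = xr.max(axis=axes, keepdims=True)
        self._mask = (xr == y)
        self._count = self._mask.sum(axis=axes, keepdims=True)
        self._in_shape = x.shape
        self._axes = axes
        return np.squeeze(y, axis=axes)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyr = np.expand_dims(dy, axis=self._axes)
        dx = self._mask * dyr / self._count  # ties share the gradient
        return dx.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        spatial = self._in_shape[2:]
        scale = 1.0 / float(np.prod(spatial))
        dy = dy.reshape(dy.shape + (1,) * len(spatial))
        return np.broadcast_to(dy * scale, self._in_shape).copy()


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype: str = "float32"):
        self.W = rng.normal(0.0, math.sqrt(1.0 / cin), size=(cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW_ps: np.ndarray | None = None
        self.db_ps: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def per_sample_grads(self) -> list[np.ndarray]:
        return [self.dW_ps, self.db_ps]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW_ps = np.einsum("bi,bo->bio", self._x, dy)
        self.db_ps = dy
        return dy @ self.W.T


class Residual(Layer):
    """y = x + f(x), f a short conv-norm-activation chain on equal width."""

    def __init__(self, inner: list[Layer]):
        self.inner = inner

    def params(self) -> list[np.ndarray]:
        return [p for l in self.inner for p in l.params()]

    def per_sample_grads(self) -> list[np.ndarray]:
        return [g for l in self.inner for g in l.per_sample_grads()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for l in self.inner:
            y = l.forward(y)
        return x + y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy
        for l in reversed(self.inner):
            dx = l.backward(dx)
        return dx + dy


# --------------------------------------------------------------------------
# network


class Network:
    """A feed-forward stack of layers with per-sample gradient collection."""

    def __init__(self, layers: list[Layer], config: ModelConfig):
        self.layers = layers
        self.config = config

    # -- parameter bookkeeping -------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def set_params(self, new: Sequence[np.ndarray]) -> None:
        flat = list(new)
        i = 0
        for l in self.layers:
            for p in l.params():
                p[...] = flat[i]
                i += 1

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def per_sample_grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.per_sample_grads()]

    def layer_kinds(self) -> list[str]:
        kinds = []
        for l in self.layers:
            kinds.append(type(l).__name__)
            if isinstance(l, Residual):
                kinds.extend(type(i).__name__ for i in l.inner)
        return kinds

    # -- compute ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch (B, C, *spatial)."""
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop per-sample loss gradients; fills per-sample param grads."""
        dy = dlogits
        for l in reversed(self.layers):
            dy = l.backward(dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid class probabilities, batched for memory."""
        x = np.asarray(x, dtype=self.config.dtype)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i: i + batch_size])
            outs.append(expit(z))
        return np.concatenate(outs, axis=0)

    def summary(self) -> str:
        lines = [f"{type(l).__name__}" for l in self.layers]
        return (
            f"Network(ndim={self.config.ndim}, widths={self.config.widths}, "
            f"activation={self.config.activation}, "
            f"n_params={self.n_params()})\n  " + "\n  ".join(lines)
        )


def build_model(cfg: ModelConfig, seed: int = 0) -> Network:
    """Build the group-normalized residual CNN described by ``cfg``.

    Layout: stem conv → [conv + pool + residual] → [conv + pool] →
    [conv + pool + residual] → global average pool → linear head; sigmoid is
    applied at inference (``predict_proba``), not stored in the graph.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D6F64]))
    w0, w1, w2, w3 = cfg.widths
    nd, act, g, dt = cfg.ndim, cfg.activation, cfg.groups, cfg.dtype

    def conv_block(cin: int, cout: int) -> list[Layer]:
        return [Conv(cin, cout, nd, rng, dtype=dt), GroupNorm(cout, g, dtype=dt),
                Activation(act)]

    layers: list[Layer] = []
    layers += conv_block(cfg.in_channels, w0)
    if cfg.stem_pool:
        layers.append(MaxPool())
    layers += conv_block(w0, w1) + [MaxPool()]
    layers.append(Residual(conv_block(w1, w1) + conv_block(w1, w1)))
    layers += conv_block(w1, w2) + [MaxPool()]
    layers += conv_block(w2, w3) + [MaxPool()]
    layers.append(Residual(conv_block(w3, w3) + conv_block(w3, w3)))
    layers.append(GlobalAvgPool())
    layers.append(Linear(w3, cfg.n_outputs, rng, dtype=cfg.dtype))
    return Network(layers, cfg)
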