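"""Minimal numpy neural-network backend.

No deep-learning framework is assumed to exist in the runtime, so the
detector and the 3D segmenter are built on these hand-written layers:
2D/3D convolutions (shift-accumulate formulation, BLAS-backed), max
pooling with exact argmax routing, nearest-neighbour upsampling, ReLU and
an Adam optimizer with global-norm gradient clipping.

Layers process one sample at a time (channel-first, no batch axis) and
cache their inputs for an immediately following ``backward`` call;
mini-batches are handled by gradient accumulation in the training loops.
All math is float32 and fully deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

try:  # fused 3x3x3 kernels; the pure-numpy path below is the reference
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    _HAVE_NUMBA = False

__all__ = [
    "Param",
    "Conv2d",
    "Conv3d",
    "ReLU",
    "MaxPool2d",
    "MaxPool3d",
    "Upsample3d",
    "Adam",
    "clip_grad_norm",
    "softmax_channels",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d:
    """Same-padded ``k x k`` convolution on ``(C, H, W)`` tensors, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.W = Param(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        _, H, W = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        out = np.empty((self.W.value.shape[0], H, W), dtype=np.float32)
        out[:] = self.b.value[:, None, None]
        for dy in range(k):
            for dx in range(k):
                out += np.tensordot(
                    self.W.value[:, :, dy, dx], xp[:, dy : dy + H, dx : dx + W], axes=([1], [0])
                )
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        _, H, W = gout.shape
        xp = self._xp
        self.b.grad += gout.sum(axis=(1, 2))
        gxp = np.zeros_like(xp)
        for dy in range(k):
            for dx in range(k):
                win = xp[:, dy : dy + H, dx : dx + W]
                self.W.grad[:, :, dy, dx] += np.tensordot(gout, win, axes=([1, 2], [1, 2]))
                gxp[:, dy : dy + H, dx : dx + W] += np.tensordot(
                    self.W.value[:, :, dy, dx].T, gout, axes=([1], [0])
                )
        return gxp[:, p : p + H, p : p + W] if p else gxp


if _HAVE_NUMBA:

    @numba.njit(fastmath=True)
    def _conv3d_fwd_k3(xp, W, b):  # pragma: no cover - exercised via Conv3d
        Cout, Cin = W.shape[0], W.shape[1]
        Z, Y, X = xp.shape[1] - 2, xp.shape[2] - 2, xp.shape[3] - 2
        out = np.empty((Cout, Z, Y, X), dtype=np.float32)
        for o in range(Cout):
            for z in range(Z):
                for y in range(Y):
                    orow = out[o, z, y]
                    for xx in range(X):
                        orow[xx] = b[o]
                    for i in range(Cin):
                        for dz in range(3):
                            for dy in range(3):
                                xrow = xp[i, z + dz, y + dy]
                                w0 = W[o, i, dz, dy, 0]
                                w1 = W[o, i, dz, dy, 1]
                                w2 = W[o, i, dz, dy, 2]
                                for xx in range(X):
                                    orow[xx] += w0 * xrow[xx] + w1 * xrow[xx + 1] + w2 * xrow[xx + 2]
        return out

    @numba.njit(fastmath=True)
    def _conv3d_gradw_k3(xp, gout):  # pragma: no cover - exercised via Conv3d
        Cout = gout.shape[0]
        Cin = xp.shape[0]
        Z, Y, X = gout.shape[1], gout.shape[2], gout.shape[3]
        gW = np.zeros((Cout, Cin, 3, 3, 3), dtype=np.float32)
        for o in range(Cout):
            for z in range(Z):
                for y in range(Y):
                    grow = gout[o, z, y]
                    for i in range(Cin):
                        for dz in range(3):
                            for dy in range(3):
                                xrow = xp[i, z + dz, y + dy]
                                s0 = np.float32(0.0)
                                s1 = np.float32(0.0)
                                s2 = np.float32(0.0)
                                for xx in range(X):
                                    g = grow[xx]
                                    s0 += g * xrow[xx]
                                    s1 += g * xrow[xx + 1]
                                    s2 += g * xrow[xx + 2]
                                gW[o, i, dz, dy, 0] += s0
                                gW[o, i, dz, dy, 1] += s1
                                gW[o, i, dz, dy, 2] += s2
        return gW


class Conv3d:
    """Same-padded ``k x k x k`` convolution on ``(C, Z, Y, X)`` tensors, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.W = Param(_he_init(rng, (cout, cin, k, k, k), cin * k**3))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        _, Z, Y, X = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        if k == 3 and _HAVE_NUMBA:
            return _conv3d_fwd_k3(
                np.ascontiguousarray(xp), self.W.value, self.b.value
            )
        out = np.empty((self.W.value.shape[0], Z, Y, X), dtype=np.float32)
        out[:] = self.b.value[:, None, None, None]
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    out += np.tensordot(
                        self.W.value[:, :, dz, dy, dx],
                        xp[:, dz : dz + Z, dy : dy + Y, dx : dx + X],
                        axes=([1], [0]),
                    )
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        _, Z, Y, X = gout.shape
        xp = self._xp
        self.b.grad += gout.sum(axis=(1, 2, 3))
        if k == 3 and _HAVE_NUMBA:
            gout_c = np.ascontiguousarray(gout.astype(np.float32, copy=False))
            xp_c = np.ascontiguousarray(xp)
            self.W.grad += _conv3d_gradw_k3(xp_c, gout_c)
            # grad wrt input = full correlation with spatially flipped,
            # in/out-transposed weights -> reuse the forward kernel
            w_flip = np.ascontiguousarray(
                self.W.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            gp = np.pad(gout_c, ((0, 0), (1, 1), (1, 1), (1, 1)))
            zeros = np.zeros(w_flip.shape[0], dtype=np.float32)
            return _conv3d_fwd_k3(gp, w_flip, zeros)
        gxp = np.zeros_like(xp)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    win = xp[:, dz : dz + Z, dy : dy + Y, dx : dx + X]
                    self.W.grad[:, :, dz, dy, dx] += np.tensordot(
                        gout, win, axes=([1, 2, 3], [1, 2, 3])
                    )
                    gxp[:, dz : dz + Z, dy : dy + Y, dx : dx + X] += np.tensordot(
                        self.W.value[:, :, dz, dy, dx].T, gout, axes=([1], [0])
                    )
        return gxp[:, p : p + Z, p : p + Y, p : p + X] if p else gxp


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool2d:
    """2x2 max pooling with exact argmax gradient routing."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"pooling requires even spatial dims, got {x.shape}")
        self._in_shape = x.shape
        v = x.reshape(C, H // 2, 2, W // 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, H // 2, W // 2, 4)
        self._idx = v.argmax(axis=-1)
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        C, H, W = self._in_shape
        gv = np.zeros((C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(gv, self._idx[..., None], gout[..., None], axis=-1)
        return gv.reshape(C, H // 2, W // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, H, W)


class MaxPool3d:
    """2x2x2 max pooling with exact argmax gradient routing."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, Z, Y, X = x.shape
        if Z % 2 or Y % 2 or X % 2:
            raise ValueError(f"pooling requires even spatial dims, got {x.shape}")
        self._in_shape = x.shape
        v = (
            x.reshape(C, Z // 2, 2, Y // 2, 2, X // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(C, Z // 2, Y // 2, X // 2, 8)
        )
        self._idx = v.argmax(axis=-1)
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        C, Z, Y, X = self._in_shape
        gv = np.zeros((C, Z // 2, Y // 2, X // 2, 8), dtype=np.float32)
        np.put_along_axis(gv, self._idx[..., None], gout[..., None], axis=-1)
        return (
            gv.reshape(C, Z // 2, Y // 2, X // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, Z, Y, X)
        )


class Upsample3d:
    """Nearest-neighbour 2x upsampling."""

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, Z, Y, X = x.shape
        out = np.empty((C, Z, 2, Y, 2, X, 2), dtype=x.dtype)
        out[...] = x[:, :, None, :, None, :, None]
        return out.reshape(C, 2 * Z, 2 * Y, 2 * X)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        C, Z, Y, X = gout.shape
        return (
            gout.reshape(C, Z // 2, 2, Y // 2, 2, X // 2, 2)
            .sum(axis=(2, 4, 6))
            .astype(np.float32)
        )


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(sum(float((p.grad**2).sum()) for p in params))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
    return norm


class Adam:
    """Adam with bias correction (the adaptive-moment optimizer)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax_channels(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    """Numerically stable softmax along a channel axis."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)
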