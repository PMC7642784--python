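"""Minimal CNN building blocks in numpy with hand-written backpropagation.

Everything runs in float32 on (N, C, H, W) tensors. Convolutions use 'same'
zero padding and are evaluated as k² shifted GEMMs via einsum, which keeps
the inner loops in BLAS. Convolution weights are re-parameterized with
weight normalization, w = g · v / ‖v‖ (per output channel), and trained with
Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "AvgPool2", "PixelShuffle2", "Adam"]

F32 = np.float32


class Conv2d:
    """Same-padding 2-D convolution with weight normalization.

    Parameters v (out, in, k, k), per-output-channel gain g and bias b. The
    effective kernel is w = g · v/‖v‖ with the norm taken over (in, k, k).
    At initialization g = ‖v‖ so w = v (He-normal).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        fan_in = c_in * kernel * kernel
        v = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.v = v.astype(F32)
        self.g = np.linalg.norm(self.v.reshape(c_out, -1), axis=1).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.kernel = kernel
        self._cache: tuple | None = None
        self.grads: dict[str, np.ndarray] = {}

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        return {"v": self.v, "g": self.g, "b": self.b}

    def set_params(self, p: dict[str, np.ndarray]) -> None:
        self.v = p["v"].astype(F32)
        self.g = p["g"].astype(F32)
        self.b = p["b"].astype(F32)

    def _effective_weight(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        norm = np.linalg.norm(self.v.reshape(self.v.shape[0], -1), axis=1)
        norm = np.maximum(norm, 1e-12).astype(F32)
        vhat = self.v / norm[:, None, None, None]
        w = self.g[:, None, None, None] * vhat
        return w, vhat, norm

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        w, vhat, norm = self._effective_weight()
        k = self.kernel
        p = k // 2
        n, c, h, wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, w.shape[0], h, wd), dtype=F32)
        for i in range(k):
            for j in range(k):
                out += np.einsum(
                    "nchw,oc->nohw", xp[:, :, i : i + h, j : j + wd], w[:, :, i, j],
                    optimize=True,
                )
        out += self.b[None, :, None, None]
        self._cache = (xp, vhat, norm, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, vhat, norm, xshape = self._cache
        n, c, h, wd = xshape
        k = self.kernel
        p = k // 2
        w = self.g[:, None, None, None] * vhat
        dw = np.zeros_like(self.v)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + h, j : j + wd]
                dw[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, patch, optimize=True)
                dxp[:, :, i : i + h, j : j + wd] += np.einsum(
                    "nohw,oc->nchw", dout, w[:, :, i, j], optimize=True
                )
        db = dout.sum(axis=(0, 2, 3))
        # weight-norm chain rule: w = g·v̂  →  dg = dw·v̂ ;  dv = (g/‖v‖)(dw − (dw·v̂)v̂)
        dg = np.einsum("ocij,ocij->o", dw, vhat)
        dv = (self.g / norm)[:, None, None, None] * (dw - dg[:, None, None, None] * vhat)
        self.grads = {"v": dv.astype(F32), "g": dg.astype(F32), "b": db.astype(F32)}
        return dxp[:, :, p : p + h, p : p + wd] if p else dxp


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(F32)


class AvgPool2:
    """2×2 average pooling (downsampling); input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5)).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        return d.astype(F32)


class PixelShuffle2:
    """Depth-to-space upsampling with factor 2: (N, 4C, H, W) → (N, C, 2H, 2W).

    Rearranging channel blocks into spatial positions avoids the checkerboard
    aliasing of transposed convolutions.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c4, h, w = x.shape
        c = c4 // 4
        self._shape = x.shape
        y = x.reshape(n, c, 2, 2, h, w).transpose(0, 1, 4, 2, 5, 3).reshape(n, c, 2 * h, 2 * w)
        return np.ascontiguousarray(y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c4, h, w = self._shape
        c = c4 // 4
        d = dout.reshape(n, c, h, 2, w, 2).transpose(0, 1, 3, 5, 2, 4).reshape(n, c4, h, w)
        return np.ascontiguousarray(d)


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in params.items():
            g = grads[key].astype(np.float64)
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
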