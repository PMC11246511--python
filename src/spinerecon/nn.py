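"""Minimal deterministic CPU neural-network layer library.

Reverse-mode gradients are written by hand per layer (``forward`` caches what
``backward`` needs; ``backward`` returns the gradient w.r.t. the layer input and
accumulates parameter gradients).  Everything is plain NumPy, single threaded
and bit-reproducible for a fixed seed, which keeps training runs testable.

Conventions
-----------
* 2D feature maps are ``[B, C, H, W]``; 3D feature maps are ``[B, C, D, H, W]``.
* Convolutions are zero-padded by ``k // 2`` ("same" for stride 1) and are
  implemented as a sum of ``k**n`` shifted einsum contractions, whose adjoint
  is the same set of shifts transposed — no im2col scatter needed.
* Parameters are created from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np

_DEFAULT_DTYPE = np.float32


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype newly constructed layers use.

    Float64 is handy for finite-difference gradient checks; float32 is the
    training default.
    """
    global _DEFAULT_DTYPE
    old = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = old


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: named sub-modules and parameters, flat registry walk."""

    def parameters(self) -> Iterator[tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                yield name, attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{i}.{sub}", p

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad[...] = 0.0

    def set_training(self, training: bool) -> None:
        for m in self.modules():
            m.training = training

    training: bool = True

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.value.copy() for name, p in self.parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                out[f"__bnstate{i}.mean"] = m.running_mean.copy()
                out[f"__bnstate{i}.var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters():
            src = state[name]
            if src.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{src.shape} vs {p.value.shape}")
            p.value = src.astype(p.value.dtype).copy()
            p.grad = np.zeros_like(p.value)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = state[f"__bnstate{i}.mean"].astype(
                    m.running_mean.dtype).copy()
                m.running_var = state[f"__bnstate{i}.var"].astype(
                    m.running_var.dtype).copy()


def _conv_out_len(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class ConvNd(Module):
    """n-dimensional convolution (n = 2 or 3) via shifted contractions."""

    def __init__(self, ndim: int, c_in: int, c_out: int, k: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 init_sd: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.ndim = ndim
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        wshape = (c_out, c_in) + (k,) * ndim
        self.weight = Parameter(
            rng.normal(0.0, init_sd, size=wshape).astype(_DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(c_out, dtype=_DEFAULT_DTYPE))
        self._eq_fwd = ("bcdhw,oc->bodhw" if ndim == 3 else "bchw,oc->bohw")
        self._eq_dw = ("bcdhw,bodhw->oc" if ndim == 3 else "bchw,bohw->oc")
        self._eq_dx = ("bodhw,oc->bcdhw" if ndim == 3 else "bohw,oc->bchw")

    def _slices(self, offsets, out_shape):
        return tuple(slice(o, o + self.stride * n, self.stride)
                     for o, n in zip(offsets, out_shape))

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p, nd = self.k, self.stride, self.pad, self.ndim
        spatial = x.shape[2:]
        out_sp = tuple(_conv_out_len(n, k, s, p) for n in spatial)
        padw = ((0, 0), (0, 0)) + ((p, p),) * nd
        xp = np.pad(x, padw)
        self._xp, self._out_sp = xp, out_sp
        y = np.zeros((x.shape[0], self.c_out) + out_sp, dtype=x.dtype)
        w = self.weight.value
        for off in np.ndindex(*(k,) * nd):
            sl = (slice(None), slice(None)) + self._slices(off, out_sp)
            y += np.einsum(self._eq_fwd, xp[sl], w[(slice(None), slice(None)) + off], optimize=True)
        y += self.bias.value.reshape((1, -1) + (1,) * nd)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p, nd = self.k, self.pad, self.ndim
        xp, out_sp = self._xp, self._out_sp
        w = self.weight.value
        dxp = np.zeros_like(xp)
        for off in np.ndindex(*(k,) * nd):
            sl = (slice(None), slice(None)) + self._slices(off, out_sp)
            widx = (slice(None), slice(None)) + off
            self.weight.grad[widx] += np.einsum(self._eq_dw, xp[sl], dy, optimize=True)
            dxp[sl] += np.einsum(self._eq_dx, dy, w[widx], optimize=True)
        self.bias.grad += dy.sum(axis=(0,) + tuple(range(2, 2 + nd)))
        if p:
            core = (slice(None), slice(None)) + (slice(p, -p),) * nd
            return dxp[core]
        return dxp


class Conv2d(ConvNd):
    def __init__(self, c_in, c_out, k=3, stride=1, rng=None, init_sd=0.02):
        super().__init__(2, c_in, c_out, k, stride, rng, init_sd)


class Conv3d(ConvNd):
    def __init__(self, c_in, c_out, k=3, stride=1, rng=None, init_sd=0.02):
        super().__init__(3, c_in, c_out, k, stride, rng, init_sd)


class BatchNorm(Module):
    """Batch normalisation over the channel axis (works for 2D and 3D maps)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=_DEFAULT_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=_DEFAULT_DTYPE))
        self.running_mean = np.zeros(channels, dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=_DEFAULT_DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        self._xhat, self._invstd, self._axes, self._shape = xhat, invstd, axes, shape
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, axes, shape = self._xhat, self._invstd, self._axes, self._shape
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value.reshape(shape)
        if not self.training:
            return dxhat * invstd.reshape(shape)
        n = dy.size // dy.shape[1]
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return invstd.reshape(shape) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Module):
    def forward(self, x):
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class Upsample3dNearest(Module):
    """Nearest-neighbour x2 upsampling; adjoint is 2x2x2 block summation."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        b, c, d, h, w = dy.shape
        return dy.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResBlock3d(Module):
    """conv-BN-ReLU-conv-BN plus (projected) identity, final ReLU."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.branch = Sequential(
            Conv3d(c_in, c_out, 3, rng=rng), BatchNorm(c_out), ReLU(),
            Conv3d(c_out, c_out, 3, rng=rng), BatchNorm(c_out))
        self.proj = (None if c_in == c_out
                     else Sequential(Conv3d(c_in, c_out, 1, rng=rng),
                                     BatchNorm(c_out)))
        self.act = ReLU()

    def forward(self, x):
        skip = x if self.proj is None else self.proj.forward(x)
        return self.act.forward(self.branch.forward(x) + skip)

    def backward(self, dy):
        dsum = self.act.backward(dy)
        dx = self.branch.backward(dsum)
        if self.proj is None:
            dx = dx + dsum
        else:
            dx = dx + self.proj.backward(dsum)
        return dx


class NonLocal2d(Module):
    """Self-attention over all spatial positions of a 2D feature map.

    For each query position the three 1x1 embeddings (theta, phi, sigma)
    produce query/key/value vectors; attention weights are a softmax over all
    N = H*W key positions; the attended values pass through an output 1x1
    projection and are added residually to the input.
    """

    def __init__(self, channels: int, inner: int | None = None, rng=None):
        inner = inner or max(1, channels // 2)
        self.channels, self.inner = channels, inner
        self.theta = Conv2d(channels, inner, 1, rng=rng)
        self.phi = Conv2d(channels, inner, 1, rng=rng)
        self.sigma = Conv2d(channels, inner, 1, rng=rng)
        self.proj = Conv2d(inner, channels, 1, rng=rng)

    def forward(self, x):
        b, c, h, w = x.shape
        n = h * w
        q = self.theta.forward(x).reshape(b, self.inner, n)  # [B,Ci,N]
        k = self.phi.forward(x).reshape(b, self.inner, n)
        v = self.sigma.forward(x).reshape(b, self.inner, n)
        logits = np.einsum("bcn,bcm->bnm", q, k)             # query n, key m
        logits -= logits.max(axis=2, keepdims=True)
        e = np.exp(logits)
        attn = e / e.sum(axis=2, keepdims=True)              # softmax over keys
        out = np.einsum("bnm,bcm->bcn", attn, v)             # attended values
        self._cache = (q, k, v, attn, (b, c, h, w))
        y = self.proj.forward(out.reshape(b, self.inner, h, w))
        return x + y

    def backward(self, dy):
        q, k, v, attn, (b, c, h, w) = self._cache
        n = h * w
        dout = self.proj.backward(dy).reshape(b, self.inner, n)
        dattn = np.einsum("bcn,bcm->bnm", dout, v)
        dv = np.einsum("bnm,bcn->bcm", attn, dout)
        # softmax jacobian, rowwise over keys
        dlogits = attn * (dattn - (dattn * attn).sum(axis=2, keepdims=True))
        dq = np.einsum("bnm,bcm->bcn", dlogits, k)
        dk = np.einsum("bnm,bcn->bcm", dlogits, q)
        dx = self.theta.backward(dq.reshape(b, self.inner, h, w))
        dx += self.phi.backward(dk.reshape(b, self.inner, h, w))
        dx += self.sigma.backward(dv.reshape(b, self.inner, h, w))
        return dx + dy


class Adam:
    """Adam with optional per-call learning rate (for scheduled decay)."""

    def __init__(self, params: list[tuple[str, Parameter]], lr: float,
                 betas: tuple[float, float] = (0.5, 0.9), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(p.value) for name, p in params}
        self.v = {name: np.zeros_like(p.value) for name, p in params}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, p in self.params:
            g = p.grad
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
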