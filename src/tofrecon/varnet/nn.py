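"""Minimal numpy neural-network layers with explicit forward/backward.

No autodiff framework is available at runtime, so every layer caches what it
needs in ``forward`` and implements its exact gradient in ``backward``
(verified against finite differences in the test suite).  Activation layout
is ``(batch, channels, *spatial)`` in float64; convolutions are stride-1
zero-padded 'same' with odd kernels, downsampling is average pooling and
upsampling is a transpose convolution whose kernel equals its stride, so no
scatter-add is ever needed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "ConvNd",
    "InstanceNorm",
    "LeakyReLU",
    "AvgPool",
    "TransposeConvNd",
    "ConvBlock",
    "TransposeConvBlock",
    "UNet",
    "NormUnet",
    "complex_to_chan",
    "chan_to_complex",
]

_LETTERS_SP = "xyz"
_LETTERS_K = "uvw"


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    def params(self) -> Iterator[Param]:
        for v in vars(self).values():
            if isinstance(v, Param):
                yield v
            elif isinstance(v, Module):
                yield from v.params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.params()


def _prod(t) -> int:
    out = 1
    for v in t:
        out *= int(v)
    return out


def _im2col(x: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    """Zero-pad 'same' and unfold: (B, C, *sp) -> (B, N, C*K)."""
    nd = x.ndim - 2
    pads = [(0, 0), (0, 0)] + [(kk // 2, kk // 2) for kk in k]
    xp = np.pad(x, pads)
    win = sliding_window_view(xp, k, axis=tuple(range(2, 2 + nd)))
    b, c = x.shape[:2]
    n = _prod(x.shape[2:])
    # (B, C, *sp, *k) -> (B, *sp, C, *k) -> (B, N, C*K): a single copy
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    return win.transpose(perm).reshape(b, n, c * _prod(k))


class ConvNd(Module):
    """Stride-1 'same' convolution (cross-correlation), optional bias."""

    def __init__(self, in_ch: int, out_ch: int, ndim: int, kernel: int, rng, bias: bool = False):
        k = (kernel,) * ndim
        fan_in = in_ch * _prod(k)
        bound = 1.0 / math.sqrt(fan_in)
        self.W = Param(rng.uniform(-bound, bound, size=(out_ch, in_ch) + k))
        self.b = Param(rng.uniform(-bound, bound, size=(out_ch,))) if bias else None
        self.ndim = ndim
        self.kernel = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        sp = x.shape[2:]
        o = self.W.value.shape[0]
        cols = _im2col(x, self.kernel)
        y = cols @ self.W.value.reshape(o, -1).T  # (B, N, O)
        if self.b is not None:
            y = y + self.b.value[None, None, :]
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape((b, o) + sp)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        b, o = g.shape[:2]
        n = _prod(g.shape[2:])
        gr = g.reshape(b, o, n).transpose(0, 2, 1)  # (B, N, O)
        self.W.grad += np.tensordot(gr, cols, axes=([0, 1], [0, 1])).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += gr.sum(axis=(0, 1))
        # input gradient = 'same' conv of g with channel-swapped, flipped W
        flip = self.W.value[(slice(None), slice(None)) + (slice(None, None, -1),) * self.ndim]
        wt = np.ascontiguousarray(np.swapaxes(flip, 0, 1))  # (C, O, *k)
        gcols = _im2col(g, self.kernel)
        gx = gcols @ wt.reshape(wt.shape[0], -1).T  # (B, N, C)
        c = xshape[1]
        self._cache = None
        return np.ascontiguousarray(gx.transpose(0, 2, 1)).reshape(xshape)


class TransposeConvNd(Module):
    """Transpose convolution with kernel == stride (non-overlapping blocks)."""

    def __init__(self, in_ch: int, out_ch: int, stride: tuple[int, ...], rng):
        nd = len(stride)
        fan_in = in_ch * _prod(stride)
        bound = 1.0 / math.sqrt(fan_in)
        self.W = Param(rng.uniform(-bound, bound, size=(out_ch, in_ch) + tuple(stride)))
        self.stride = tuple(stride)
        sp = _LETTERS_SP[:nd]
        kr = _LETTERS_K[:nd]
        inter = "".join(a + b for a, b in zip(sp, kr))
        self._fwd = f"bc{sp},oc{kr}->bo{inter}"
        self._bwd_w = f"bo{inter},bc{sp}->oc{kr}"
        self._bwd_x = f"bo{inter},oc{kr}->bc{sp}"

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        o = self.W.value.shape[0]
        sp = x.shape[2:]
        y = np.einsum(self._fwd, x, self.W.value)
        self._cache = x
        out_sp = tuple(s * k for s, k in zip(sp, self.stride))
        return y.reshape((b, o) + out_sp)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        b, o = g.shape[:2]
        blocks = []
        for s, k in zip(x.shape[2:], self.stride):
            blocks.extend([s, k])
        gb = g.reshape((b, o) + tuple(blocks))
        self.W.grad += np.einsum(self._bwd_w, gb, x)
        self._cache = None
        return np.einsum(self._bwd_x, gb, self.W.value)


class InstanceNorm(Module):
    """Per-(batch, channel) normalization over spatial axes, no affine."""

    eps = 1e-5

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes)
        return xhat

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        self._cache = None
        return inv * (g - gm - xhat * gxm)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x >= 0
        self._cache = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        mask = self._cache
        self._cache = None
        return np.where(mask, g, self.slope * g)


class AvgPool(Module):
    def __init__(self, stride: tuple[int, ...]):
        self.stride = tuple(stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c = x.shape[:2]
        shape = [b, c]
        axes = []
        for i, (s, k) in enumerate(zip(x.shape[2:], self.stride)):
            assert s % k == 0, f"extent {s} not divisible by pool {k}"
            shape.extend([s // k, k])
            axes.append(2 + 2 * i + 1)
        self._cache = x.shape
        return x.reshape(shape).mean(axis=tuple(axes))

    def backward(self, g: np.ndarray) -> np.ndarray:
        xshape = self._cache
        self._cache = None
        scale = 1.0 / _prod(self.stride)
        out = g
        for i, k in enumerate(self.stride):
            out = np.repeat(out, k, axis=2 + i)
        return out.reshape(xshape) * scale


class ConvBlock(Module):
    """conv -> instance norm -> leaky ReLU, twice (bias-free convs)."""

    def __init__(self, in_ch: int, out_ch: int, ndim: int, rng):
        self.layers = [
            ConvNd(in_ch, out_ch, ndim, 3, rng),
            InstanceNorm(),
            LeakyReLU(),
            ConvNd(out_ch, out_ch, ndim, 3, rng),
            InstanceNorm(),
            LeakyReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class TransposeConvBlock(Module):
    """transpose conv (kernel==stride) -> instance norm -> leaky ReLU."""

    def __init__(self, in_ch: int, out_ch: int, stride: tuple[int, ...], rng):
        self.layers = [TransposeConvNd(in_ch, out_ch, stride, rng), InstanceNorm(), LeakyReLU()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet(Module):
    """Encoder/decoder with skip connections and per-level pooling strides.

    ``strides[i]`` is the pooling stride tuple applied after encoder level
    ``i``; decoder levels mirror them in reverse, with transpose-conv kernels
    equal to the corresponding strides.  Channel width doubles per level.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        chans: int,
        strides: list[tuple[int, ...]],
        rng,
    ):
        ndim = len(strides[0])
        self.ndim = ndim
        self.strides = [tuple(s) for s in strides]
        levels = len(strides)
        self.down_blocks = []
        ch = chans
        self.down_blocks.append(ConvBlock(in_ch, chans, ndim, rng))
        for _ in range(levels - 1):
            self.down_blocks.append(ConvBlock(ch, ch * 2, ndim, rng))
            ch *= 2
        self.pools = [AvgPool(s) for s in self.strides]
        self.bottleneck = ConvBlock(ch, ch * 2, ndim, rng)
        self.up_transpose = []
        self.up_blocks = []
        for s in reversed(self.strides):
            self.up_transpose.append(TransposeConvBlock(ch * 2, ch, s, rng))
            self.up_blocks.append(ConvBlock(ch * 2, ch, ndim, rng))
            ch //= 2
        # the last up block keeps width `chans`, then a 1x1 conv maps out
        self.final_conv = ConvNd(chans, out_ch, ndim, 1, rng, bias=True)

    @property
    def divisors(self) -> tuple[int, ...]:
        div = [1] * self.ndim
        for s in self.strides:
            for i, k in enumerate(s):
                div[i] *= k
        return tuple(div)

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        out = x
        for block, pool in zip(self.down_blocks, self.pools):
            out = block.forward(out)
            skips.append(out)
            out = pool.forward(out)
        out = self.bottleneck.forward(out)
        for tblock, block in zip(self.up_transpose, self.up_blocks):
            out = tblock.forward(out)
            skip = skips.pop()
            out = np.concatenate([out, skip], axis=1)
            out = block.forward(out)
        return self.final_conv.forward(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.final_conv.backward(g)
        skip_grads = []
        for tblock, block in zip(reversed(self.up_transpose), reversed(self.up_blocks)):
            g = block.backward(g)
            half = g.shape[1] // 2
            skip_grads.append(g[:, half:])
            g = tblock.backward(np.ascontiguousarray(g[:, :half]))
        g = self.bottleneck.backward(g)
        for block, pool in zip(reversed(self.down_blocks), reversed(self.pools)):
            g = pool.backward(g)
            g = g + skip_grads.pop()
            g = block.backward(g)
        return g


def _reflect_index(n: int, pad: int) -> np.ndarray:
    mode = "reflect" if (n > 1 and pad <= n - 1) else "edge"
    return np.pad(np.arange(n), (0, pad), mode=mode)


class NormUnet(Module):
    """U-Net wrapper: per-item whole-tensor normalization and padding of the
    spatial extents to the U-Net's pooling divisors (gradient-exact)."""

    eps = 1e-8

    def __init__(self, in_ch: int, out_ch: int, chans: int, strides: list[tuple[int, ...]], rng):
        self.unet = UNet(in_ch, out_ch, chans, strides, rng)

    def _pads(self, sp: tuple[int, ...]) -> list[int]:
        div = self.unet.divisors
        return [(d - s % d) % d for s, d in zip(sp, div)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        sigma = np.sqrt(var + self.eps)
        xhat = (x - mu) / sigma

        sp = x.shape[2:]
        pads = self._pads(sp)
        xp = xhat
        idxs = []
        for ax, pad in enumerate(pads):
            if pad:
                idx = _reflect_index(sp[ax], pad)
                xp = np.take(xp, idx, axis=2 + ax)
                idxs.append((ax, idx))
        u = self.unet.forward(xp)
        u = u[(slice(None), slice(None)) + tuple(slice(0, s) for s in sp)]
        out = u * sigma + mu
        self._cache = (x, xhat, mu, sigma, u, axes, sp, pads, idxs)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, xhat, mu, sigma, u, axes, sp, pads, idxs = self._cache
        self._cache = None
        n = _prod(x.shape[1:])
        # out = u * sigma + mu, with u = U(xhat), xhat = (x - mu)/sigma
        g_u = g * sigma
        g_sigma = (g * u).sum(axis=axes, keepdims=True)
        g_mu = g.sum(axis=axes, keepdims=True)

        # pad g_u back up, run U-Net backward, fold pad gradients back down
        gu_p = np.zeros(g_u.shape[:2] + tuple(s + p for s, p in zip(sp, pads)), dtype=g_u.dtype)
        gu_p[(slice(None), slice(None)) + tuple(slice(0, s) for s in sp)] = g_u
        g_xp = self.unet.backward(gu_p)
        for ax, idx in reversed(idxs):
            moved = np.moveaxis(g_xp, 2 + ax, 0)
            folded = np.zeros((sp[ax],) + moved.shape[1:], dtype=moved.dtype)
            np.add.at(folded, idx, moved)
            g_xp = np.moveaxis(folded, 0, 2 + ax)
        g_xhat = g_xp

        # xhat = (x - mu)/sigma
        g_sigma = g_sigma + (g_xhat * (-(x - mu) / sigma**2)).sum(axis=axes, keepdims=True)
        g_mu = g_mu + (-g_xhat / sigma).sum(axis=axes, keepdims=True)
        g_x = g_xhat / sigma
        # sigma = sqrt(var + eps), var/mu over all non-batch axes
        g_x = g_x + g_sigma * (x - mu) / (n * sigma)
        g_x = g_x + g_mu / n
        return g_x


def complex_to_chan(z: np.ndarray) -> np.ndarray:
    """Complex (B, *sp) -> real (B, 2, *sp), channels (real, imag)."""
    return np.stack([z.real, z.imag], axis=1)


def chan_to_complex(x: np.ndarray) -> np.ndarray:
    """Real (B, 2, *sp) -> complex (B, *sp)."""
    return x[:, 0] + 1j * x[:, 1]
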