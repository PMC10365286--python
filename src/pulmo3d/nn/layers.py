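"""Layers: N-dimensional convolution (2D/3D), block-transposed convolution,
factor max-pooling, batch norm, ReLU, linear.

Convolutions run as im2col + one BLAS matmul, which is the fastest route for
the small feature maps this package trains on a single CPU core. The im2col
buffer is cached for the backward pass; col2im scatters gradients with one
strided addition per kernel offset (<= 27 for 3x3x3).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter, he_init


def _tupled(v, nd):
    return tuple(v) if isinstance(v, (tuple, list)) else (v,) * nd


class ConvNd(Module):
    """Cross-correlation over ``nd`` spatial dims (channels-first layout)."""

    def __init__(self, nd, in_ch, out_ch, kernel, stride=1, padding=0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.nd = nd
        self.kernel = _tupled(kernel, nd)
        self.stride = _tupled(stride, nd)
        self.padding = _tupled(padding, nd)
        fan_in = in_ch * int(np.prod(self.kernel))
        self.weight = Parameter(he_init(rng, (out_ch, in_ch) + self.kernel, fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self._cache = None

    def _is_pointwise(self):
        return all(ki == 1 for ki in self.kernel) \
            and all(si == 1 for si in self.stride) and not any(self.padding)

    def forward(self, x, train: bool = True):
        nd, k, s, p = self.nd, self.kernel, self.stride, self.padding
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, c = x.shape[:2]
        if self._is_pointwise():
            # 1x1 conv: a single channel-mixing GEMM, no im2col buffer
            wmat = self.weight.data.reshape(self.weight.shape[0], c)
            out = np.tensordot(wmat, x, axes=([1], [1]))  # (Cout, n, *sp)
            out = np.moveaxis(out, 0, 1)
            if self.bias is not None:
                out += self.bias.data.reshape((1, -1) + (1,) * nd)
            if train:
                self._cache = ("pointwise", x)
            return np.ascontiguousarray(out)
        pad = [(0, 0), (0, 0)] + [(pi, pi) for pi in p]
        xp = np.pad(x, pad) if any(p) else x
        win = sliding_window_view(xp, k, axis=tuple(range(2, 2 + nd)))
        win = win[(slice(None), slice(None))
                  + tuple(slice(None, None, si) for si in s)]
        out_sp = win.shape[2:2 + nd]
        # (n, *out, c, *k) -> rows are output positions, cols are receptive field
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
        cols = np.ascontiguousarray(win.transpose(perm)).reshape(
            n * int(np.prod(out_sp)), c * int(np.prod(k)))
        wmat = self.weight.data.reshape(self.weight.shape[0], -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape((n,) + tuple(out_sp) + (-1,))
        out = np.moveaxis(out, -1, 1)
        if train:
            self._cache = ("im2col", cols, x.shape, xp.shape, out_sp)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        if self._cache[0] == "pointwise":
            _, x = self._cache
            self._cache = None
            nd = self.nd
            c_out, c_in = self.weight.shape[:2]
            sum_axes = (0,) + tuple(range(2, 2 + nd))
            self.weight.grad += np.tensordot(
                grad, x, axes=(sum_axes, sum_axes)).reshape(self.weight.shape)
            if self.bias is not None:
                self.bias.grad += grad.sum(axis=sum_axes)
            wmat = self.weight.data.reshape(c_out, c_in)
            dx = np.tensordot(wmat.T, grad, axes=([1], [1]))
            return np.ascontiguousarray(np.moveaxis(dx, 0, 1))
        _, cols, x_shape, xp_shape, out_sp = self._cache
        self._cache = None
        nd, k, s, p = self.nd, self.kernel, self.stride, self.padding
        n, c = x_shape[:2]
        out_ch = self.weight.shape[0]
        gmat = np.ascontiguousarray(
            np.moveaxis(grad, 1, -1)).reshape(-1, out_ch)
        wmat = self.weight.data.reshape(out_ch, -1)
        self.weight.grad += (gmat.T @ cols).reshape(self.weight.shape)
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=0)
        dcols = (gmat @ wmat).reshape((n,) + tuple(out_sp) + (c,) + k)
        # scatter back into the padded input, one strided add per kernel offset
        perm = (0, 1 + nd) + tuple(range(1, 1 + nd)) + tuple(range(2 + nd, 2 + 2 * nd))
        dcols = dcols.transpose(perm)  # (n, c, *out, *k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for idx in product(*(range(ki) for ki in k)):
            sl = tuple(slice(i, i + si * o, si)
                       for i, si, o in zip(idx, s, out_sp))
            dxp[(slice(None), slice(None)) + sl] += dcols[
                (slice(None), slice(None)) + (slice(None),) * nd + idx]
        if any(p):
            sl = tuple(slice(pi, dim - pi) for pi, dim in zip(p, xp_shape[2:]))
            dxp = dxp[(slice(None), slice(None)) + sl]
        return dxp


def Conv2d(in_ch, out_ch, kernel, stride=1, padding=0, rng=None, bias=True):
    return ConvNd(2, in_ch, out_ch, kernel, stride, padding, rng, bias)


def Conv3d(in_ch, out_ch, kernel, stride=1, padding=0, rng=None, bias=True):
    return ConvNd(3, in_ch, out_ch, kernel, stride, padding, rng, bias)


class BlockDeconvNd(Module):
    """Transposed convolution with kernel == stride == ``factor``.

    Each input voxel expands into a learned ``factor**nd`` block, so output
    blocks never overlap; this is the learnable upsampler used to merge
    coarse pyramid levels into finer ones.
    """

    def __init__(self, nd, in_ch, out_ch, factor,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.nd = nd
        self.factor = f = _tupled(factor, nd)
        self.weight = Parameter(he_init(rng, (in_ch, out_ch) + f, in_ch))
        self.bias = Parameter(np.zeros(out_ch))
        self._cache = None

    def forward(self, x, train: bool = True):
        nd, f = self.nd, self.factor
        x = np.ascontiguousarray(x, dtype=np.float32)
        n = x.shape[0]
        sp = x.shape[2:]
        tmp = np.tensordot(x, self.weight.data, axes=([1], [0]))
        # tmp: (n, *sp, out_ch, *f) -> interleave spatial and factor axes
        perm = (0, 1 + nd) + sum(((1 + i, 2 + nd + i) for i in range(nd)), ())
        out = tmp.transpose(perm).reshape(
            (n, self.weight.shape[1]) + tuple(s * fi for s, fi in zip(sp, f)))
        out = out + self.bias.data.reshape((1, -1) + (1,) * nd)
        if train:
            self._cache = (x, sp)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        x, sp = self._cache
        self._cache = None
        nd, f = self.nd, self.factor
        n = grad.shape[0]
        out_ch = self.weight.shape[1]
        # un-interleave back to (n, *sp, out_ch, *f)
        shaped = grad.reshape((n, out_ch) + sum(
            ((s, fi) for s, fi in zip(sp, f)), ()))
        perm = (0,) + tuple(2 + 2 * i for i in range(nd)) + (1,) \
            + tuple(3 + 2 * i for i in range(nd))
        dtmp = np.ascontiguousarray(shaped.transpose(perm))
        ax_sp = tuple(range(1, 1 + nd))
        self.weight.grad += np.tensordot(x, dtmp, axes=([0] + [2 + i for i in range(nd)],
                                                        [0] + list(ax_sp)))
        self.bias.grad += grad.sum(axis=(0,) + tuple(range(2, 2 + nd)))
        dx = np.tensordot(dtmp, self.weight.data,
                          axes=(list(range(1 + nd, 2 + 2 * nd)), [1] + list(range(2, 2 + nd))))
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class MaxPoolNd(Module):
    """Non-overlapping max pooling by an integer factor per spatial axis."""

    def __init__(self, nd, factor):
        super().__init__()
        self.nd = nd
        self.factor = _tupled(factor, nd)
        self._cache = None

    def forward(self, x, train: bool = True):
        nd, f = self.nd, self.factor
        n, c = x.shape[:2]
        sp = x.shape[2:]
        if any(s % fi for s, fi in zip(sp, f)):
            raise ValueError(f"spatial shape {sp} not divisible by pool factor {f}")
        out_sp = tuple(s // fi for s, fi in zip(sp, f))
        shaped = x.reshape((n, c) + sum(((o, fi) for o, fi in zip(out_sp, f)), ()))
        perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) \
            + tuple(3 + 2 * i for i in range(nd))
        blocks = np.ascontiguousarray(shaped.transpose(perm)).reshape(
            (n, c) + out_sp + (int(np.prod(f)),))
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, out_sp, perm, blocks.shape)
        return out

    def backward(self, grad):
        idx, x_shape, out_sp, perm, blocks_shape = self._cache
        self._cache = None
        gb = np.zeros(blocks_shape, dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], grad[..., None], axis=-1)
        nd, f = self.nd, self.factor
        n, c = x_shape[:2]
        gb = gb.reshape((n, c) + out_sp + tuple(f))
        inv = np.argsort(perm)
        shaped = gb.transpose(inv)
        return shaped.reshape(x_shape)


class BatchNorm(Module):
    """Batch normalization over batch + spatial axes (channels axis 1)."""

    def __init__(self, num_ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)
        self._cache = None

    def extra_state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train: bool = True):
        axes = (0,) + tuple(range(2, x.ndim))
        bs = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv_std.reshape(bs)
        out = self.gamma.data.reshape(bs) * xhat + self.beta.data.reshape(bs)
        if train:
            self._cache = (xhat, inv_std, axes, bs)
        return out.astype(np.float32)

    def backward(self, grad):
        xhat, inv_std, axes, bs = self._cache
        self._cache = None
        m = float(np.prod([grad.shape[a] for a in axes]))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.data.reshape(bs)
        dx = (g - g.mean(axis=axes, keepdims=True)
              - xhat * (g * xhat).sum(axis=axes, keepdims=True) / m)
        return (dx * inv_std.reshape(bs)).astype(np.float32)


def recalibrate_bn(model: Module, batches) -> None:
    """Re-estimate batch-norm running statistics over ``batches``.

    Short training runs leave the momentum-averaged running statistics far
    from the activation distribution the final weights produce, which ruins
    eval-mode predictions. This pass replaces them with the exact mean of
    the per-batch statistics under the final weights (momentum 1/(i+1)
    implements a cumulative average), then restores each layer's momentum.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    for i, batch in enumerate(batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        model.forward(batch, train=True)
    for bn, momentum in zip(bns, saved):
        bn.momentum = momentum
        bn._cache = None


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train: bool = True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        mask, self._mask = self._mask, None
        return grad * mask


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features))
        self._x = None

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        x, self._x = self._x, None
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Flatten(Module):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool(Module):
    """Mean over all spatial axes -> (n, c)."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad):
        shape = self._shape
        n_sp = int(np.prod(shape[2:]))
        g = grad.reshape(shape[:2] + (1,) * (len(shape) - 2))
        return np.broadcast_to(g / n_sp, shape).astype(np.float32)
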