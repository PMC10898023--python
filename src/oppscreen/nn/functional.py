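"""Differentiable operations used by the networks.

Convolutions use im2col + BLAS matmul with fast paths for 1x1 kernels
and for the non-overlapping 2x2/stride-2 case that the encoder-decoder
uses for down/up-sampling.  All arrays are float32, NCHW layout.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "conv2d", "conv_transpose2d", "relu", "sigmoid", "add", "channel_scale",
    "concat_channels", "max_pool2d", "global_avg_pool", "linear",
    "batch_norm2d", "dice_bce_loss", "cross_entropy",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,Hp,Wp) -> windows (N,Ho,Wo,C,kh,kw) as a contiguous copy."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (N,C,Ho,Wo,kh,kw)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); w is (O, C, kh, kw)."""
    o, c, kh, kw = w.shape
    n, cx, h, wd = x.shape
    if cx != c:
        raise ValueError(f"channel mismatch: input {cx}, weight {c}")
    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    cols2 = cols.reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out = cols2 @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        gout = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        if w.requires_grad:
            w.accumulate_grad((gout.T @ cols2).reshape(o, c, kh, kw))
        if b is not None and b.requires_grad:
            b.accumulate_grad(gout.sum(axis=0))
        if x.requires_grad:
            gcols = (gout @ wmat).reshape(n, ho, wo, c, kh, kw)
            hp, wp = h + 2 * padding, wd + 2 * padding
            gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            for ki in range(kh):
                for kj in range(kw):
                    gxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += \
                        gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
            x.accumulate_grad(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor.make(out, parents, backward)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    n, c, h, wd = x.shape
    o = w.shape[0]
    wmat = w.data.reshape(o, c)
    out = np.einsum("oc,nchw->nohw", wmat, x.data, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("nohw,nchw->oc", g, x.data, optimize=True)
            w.accumulate_grad(gw.reshape(o, c, 1, 1))
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x.accumulate_grad(np.einsum("oc,nohw->nchw", wmat, g, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor.make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (no overlap); w is (C, O, k, k)."""
    c, o, kh, kw = w.shape
    if kh != stride or kw != stride:
        raise ValueError("conv_transpose2d supports kernel == stride only")
    n, cx, h, wd = x.shape
    if cx != c:
        raise ValueError(f"channel mismatch: input {cx}, weight {c}")
    # y[n,o,h*s+ki,w*s+kj] = sum_c x[n,c,h,w] * w[c,o,ki,kj]
    tmp = np.tensordot(x.data, w.data, axes=([1], [0]))    # (N,H,W,O,kh,kw)
    out = np.ascontiguousarray(tmp.transpose(0, 3, 1, 4, 2, 5)).reshape(
        n, o, h * stride, wd * stride)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gr = g.reshape(n, o, h, stride, wd, stride).transpose(0, 2, 4, 1, 3, 5)
        if w.requires_grad:
            gw = np.tensordot(x.data, gr, axes=([0, 2, 3], [0, 1, 2]))
            w.accumulate_grad(gw)                          # (C,O,kh,kw)
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.tensordot(gr, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x.accumulate_grad(gx.transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor.make(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * mask)

    return Tensor.make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * out * (1.0 - out))

    return Tensor.make(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in add: {a.shape} vs {b.shape}")
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g)
        if b.requires_grad:
            b.accumulate_grad(g)

    return Tensor.make(out, (a, b), backward)


def channel_scale(weights: Tensor, x: Tensor) -> Tensor:
    """Per-channel reweighting: weights (N,C,1,1) * x (N,C,H,W)."""
    out = weights.data * x.data

    def backward(g):
        if weights.requires_grad:
            weights.accumulate_grad((g * x.data).sum(axis=(2, 3), keepdims=True))
        if x.requires_grad:
            x.accumulate_grad(g * weights.data)

    return Tensor.make(out, (weights, x), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    if a.shape[0] != b.shape[0] or a.shape[2:] != b.shape[2:]:
        raise ValueError(f"spatial/batch mismatch in concat: {a.shape} vs {b.shape}")
    ca = a.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g[:, :ca])
        if b.requires_grad:
            b.accumulate_grad(g[:, ca:])

    return Tensor.make(out, (a, b), backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    hp, wp = xp.shape[2:]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(n, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        ni, ci, hi, wi = np.indices((n, c, ho, wo), sparse=False)
        rows = hi * stride + idx // kernel
        cols = wi * stride + idx % kernel
        np.add.at(gxp, (ni, ci, rows, cols), g)
        if padding:
            gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
        x.accumulate_grad(gxp)

    return Tensor.make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(
                (g / (h * w))[:, :, None, None], x.shape).astype(np.float32))

    return Tensor.make(out, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """x (N,F) @ w (F,O) + b."""
    out = x.data @ w.data
    if b is not None:
        out += b.data

    def backward(g):
        if w.requires_grad:
            w.accumulate_grad(x.data.T @ g)
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=0))
        if x.requires_grad:
            x.accumulate_grad(g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor.make(out, parents, backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Training-mode batch normalisation over (N,H,W) per channel.

    Returns (out, batch_mean, batch_var) — the caller updates running stats.
    """
    n, c, h, w = x.shape
    m = n * h * w
    mu = x.data.mean(axis=(0, 2, 3))
    var = x.data.var(axis=(0, 2, 3))
    ivar = 1.0 / np.sqrt(var + eps)
    xc = x.data - mu[None, :, None, None]
    xhat = xc * ivar[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            s1 = gxhat.sum(axis=(0, 2, 3))
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3))
            gx = (gxhat - (s1[None, :, None, None] + xhat * s2[None, :, None, None]) / m) \
                * ivar[None, :, None, None]
            x.accumulate_grad(gx.astype(np.float32))

    return Tensor.make(out, (x, gamma, beta), backward), mu, var


def dice_bce_loss(logits: Tensor, targets: np.ndarray,
                  dice_weight: float = 1.0, bce_weight: float = 1.0,
                  eps: float = 1.0) -> Tensor:
    """Soft-Dice + binary cross-entropy on foreground logits.

    ``targets`` is a {0,1} array of the same shape as ``logits``.
    Dice is computed per sample and averaged; BCE is the per-pixel mean.
    """
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != logits.shape:
        raise ValueError("logits/targets shape mismatch")
    z = logits.data
    p = 1.0 / (1.0 + np.exp(-z))
    n = z.shape[0]
    axes = tuple(range(1, z.ndim))
    inter = (p * t).sum(axis=axes)
    psum = p.sum(axis=axes)
    tsum = t.sum(axis=axes)
    num = 2.0 * inter + eps
    den = psum + tsum + eps
    dice = num / den
    # numerically stable BCE: max(z,0) - z*t + log(1+exp(-|z|))
    bce = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    loss = bce_weight * bce + dice_weight * (1.0 - dice.mean())

    def backward(g):
        if not logits.requires_grad:
            return
        gscalar = float(g)
        gz = bce_weight * (p - t) / z.size
        # d(1 - mean dice)/dp_i = -(1/n) * (2 t_i * den - num) / den^2, per sample
        shape = (n,) + (1,) * (z.ndim - 1)
        dd = (2.0 * t * den.reshape(shape) - num.reshape(shape)) / (den ** 2).reshape(shape)
        gz += dice_weight * (-dd / n) * p * (1.0 - p)
        logits.accumulate_grad(gscalar * gz)

    return Tensor.make(np.float32(loss), (logits,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted softmax cross-entropy; logits (N,K), integer labels (N,)."""
    z = logits.data
    n, k = z.shape
    lab = np.asarray(labels, dtype=np.intp)
    zs = z - z.max(axis=1, keepdims=True)
    ez = np.exp(zs)
    probs = ez / ez.sum(axis=1, keepdims=True)
    logp = zs - np.log(ez.sum(axis=1, keepdims=True))
    wvec = np.ones(n, dtype=np.float32) if class_weights is None \
        else np.asarray(class_weights, dtype=np.float32)[lab]
    wsum = wvec.sum()
    loss = -(wvec * logp[np.arange(n), lab]).sum() / wsum

    def backward(g):
        if not logits.requires_grad:
            return
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), lab] = 1.0
        gz = (probs - onehot) * (wvec / wsum)[:, None]
        logits.accumulate_grad(float(g) * gz)

    return Tensor.make(np.float32(loss), (logits,), backward)
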