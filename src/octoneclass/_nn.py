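"""Minimal NumPy CNN engine used by the segmentation network.

Implements exactly the primitives the U-Net needs — 3x3 same-padding
convolution, ReLU, 2x2 max pooling, nearest-neighbour 2x upsampling, channel
concatenation, pixelwise softmax cross-entropy and the Adam optimiser — with
hand-derived backward passes.

Tensors are float32 and channels-last: (batch, height, width, channels).
With this layout the im2col patch matrix of a same-padded convolution is a
concatenation of k*k shifted slices, each a contiguous row-wise copy, so the
whole convolution reduces to one BLAS matmul with negligible gather cost.
The input gradient of a stride-1 same-padding convolution is itself a
convolution with the spatially flipped, channel-transposed kernel; the
weight gradient re-derives the patch matrix from the cached layer input, so
no large intermediate is retained between forward and backward.

Everything here is deterministic: randomness enters only through the
`numpy.random.Generator` handed to the initialisers.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# convolution


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Stride-1 same-padding convolution; kh, kw odd.

    x: (B,H,W,Cin); W: (Cout,Cin,kh,kw).  Returns (out, cache); the cache
    holds only references to x and W.

    Computed by shift-and-accumulate: one (Cin x Cout) matmul per kernel
    offset on a shifted view of the padded input.  This keeps every flop in
    BLAS without materialising an interleaved im2col matrix.
    """
    B, H, Wd, C = x.shape
    Cout, Cin, kh, kw = W.shape
    assert C == Cin, (C, Cin)
    if kh == 1 and kw == 1:
        out = x @ np.ascontiguousarray(W[:, :, 0, 0].T, dtype=DTYPE)
        out += b
        return out, (x, W)
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.empty((B, H, Wd, Cout), dtype=DTYPE)
    out[...] = b
    for i in range(kh):
        for j in range(kw):
            wk = np.ascontiguousarray(W[:, :, i, j].T, dtype=DTYPE)
            out += xp[:, i:i + H, j:j + Wd, :] @ wk
    return out, (x, W)


def conv2d_backward(dout: np.ndarray, cache):
    """Gradients of conv2d_forward w.r.t. input, weights and bias."""
    x, W = cache
    B, H, Wd, Cin = x.shape
    Cout, _, kh, kw = W.shape
    dout_mat = np.ascontiguousarray(dout, dtype=DTYPE).reshape(B * H * Wd, Cout)
    db = dout_mat.sum(axis=0)
    if kh == 1 and kw == 1:
        dW = (dout_mat.T @ x.reshape(-1, Cin))[:, :, None, None]
        dx = dout @ np.ascontiguousarray(W[:, :, 0, 0], dtype=DTYPE)
        return dx, np.ascontiguousarray(dW, dtype=DTYPE), db.astype(DTYPE)
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    dW = np.empty_like(W)
    for i in range(kh):
        for j in range(kw):
            sl = np.ascontiguousarray(xp[:, i:i + H, j:j + Wd, :])
            dW[:, :, i, j] = dout_mat.T @ sl.reshape(-1, Cin)
    # dX: correlate dout with the flipped, channel-transposed kernel.
    Wt = np.ascontiguousarray(
        W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3), dtype=DTYPE)
    dx, _ = conv2d_forward(dout, Wt, np.zeros(Cin, dtype=DTYPE))
    return dx, dW, db.astype(DTYPE)


# ---------------------------------------------------------------------------
# elementwise / structural layers


def relu_forward(x):
    out = np.maximum(x, 0)
    return out, (x > 0)


def relu_backward(dout, mask):
    return dout * mask


_POOL_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


def maxpool2_forward(x):
    """2x2 max pooling, stride 2; H and W must be even.  x: (B,H,W,C)."""
    quads = [x[:, i::2, j::2, :] for i, j in _POOL_OFFSETS]
    out = np.maximum(np.maximum(quads[0], quads[1]),
                     np.maximum(quads[2], quads[3]))
    return out, (x, out)


def maxpool2_backward(dout, cache):
    """Routes each pooled gradient to the first maximal element of its
    window (fixed tie-break, matching the forward's effective choice)."""
    x, out = cache
    dx = np.zeros_like(x)
    assigned = np.zeros(out.shape, dtype=bool)
    for i, j in _POOL_OFFSETS:
        sl = x[:, i::2, j::2, :]
        m = (sl == out) & ~assigned
        dx[:, i::2, j::2, :][m] = dout[m]
        assigned |= m
    return dx


def upsample2_forward(x):
    """Nearest-neighbour 2x upsampling along both spatial axes."""
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def upsample2_backward(dout):
    B, H2, W2, C = dout.shape
    return dout.reshape(B, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4))


def concat_forward(a, b):
    return np.concatenate([a, b], axis=3), a.shape[3]


def concat_backward(dout, split):
    return (np.ascontiguousarray(dout[..., :split]),
            np.ascontiguousarray(dout[..., split:]))


# ---------------------------------------------------------------------------
# loss


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Pixelwise cross-entropy, mean over batch and pixels.

    logits: (B, H, W, K); labels: (B, H, W) integer class indices.  With
    ``class_weights`` (length K) each pixel's term is weighted by its true
    class's weight and the mean is weight-normalised.  Returns
    (loss, dlogits).
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z, dtype=np.float64)
    p = ez / ez.sum(axis=-1, keepdims=True)
    idx = labels[..., None]
    p_true = np.take_along_axis(p, idx, axis=-1)[..., 0]
    dlogits = p.astype(DTYPE)
    np.put_along_axis(
        dlogits, idx,
        np.take_along_axis(dlogits, idx, axis=-1) - 1.0, axis=-1)
    if class_weights is None:
        n = labels.size
        loss = -np.log(p_true).mean()
        dlogits /= n
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        wsum = w.sum()
        loss = -(w * np.log(p_true)).sum() / wsum
        dlogits *= (w / wsum)[..., None].astype(DTYPE)
    return float(loss), dlogits


# ---------------------------------------------------------------------------
# parameters and optimiser


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def he_conv(rng: np.random.Generator, cout: int, cin: int, k: int) -> Param:
    """He-normal initialised conv kernel (fan_in = cin * k * k)."""
    std = np.sqrt(2.0 / (cin * k * k))
    return Param(rng.standard_normal((cout, cin, k, k)) * std)


class Adam:
    """Adaptive moment estimation over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bias1)
                        / (np.sqrt(v / bias2) + self.eps)).astype(DTYPE)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0
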