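"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The SR networks in this package are plain feed-forward DAGs built from a
small fixed vocabulary of operations (stride-1 convolutions, ReLU, sigmoid,
linear layers, global average pooling, pixel shuffle, broadcast add/mul and
an L1 reduction), so a compact tape-based engine is sufficient: each op
records a backward closure, and ``Tensor.backward`` runs them in reverse
topological order. All computation is float32.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

DTYPE = np.float32


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, _prev=(a, b), _backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _prev=(a, b), _backward=backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * s)

    return Tensor(a.data * s, _prev=(a,), _backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(a.data * mask, _prev=(a,), _backward=backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, _prev=(a,), _backward=backward)


def replicate_pad(x: Tensor, p: int) -> Tensor:
    """Edge-replicating spatial padding of an NCHW tensor.

    The backward pass folds the gradient of each replicated border cell
    back onto the edge pixel it copies.
    """
    if p == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            g = g.copy()
            g[:, :, p, :] += g[:, :, :p, :].sum(axis=2)
            g[:, :, -p - 1, :] += g[:, :, -p:, :].sum(axis=2)
            core = g[:, :, p:-p, :]
            core[:, :, :, p] += core[:, :, :, :p].sum(axis=3)
            core[:, :, :, -p - 1] += core[:, :, :, -p:].sum(axis=3)
            x._accumulate(core[:, :, :, p:-p])

    return Tensor(out_data, _prev=(x,), _backward=backward)


def _pad_channels_last(x: np.ndarray, pad: int) -> np.ndarray:
    """(N, C, H, W) → contiguous (N, H+2p, W+2p, C)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return np.ascontiguousarray(x.transpose(0, 2, 3, 1))


def _conv2d_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation; x (N,Cin,H,W), w (Cout,Cin,kh,kw).

    Computed as a sum of kernel-offset matmuls on a channels-last copy —
    much cheaper than materializing an im2col matrix for small kernels.
    """
    cout, cin, kh, kw = w.shape
    n, _, h, ww = x.shape
    xt = _pad_channels_last(x, pad)
    oh, ow = h + 2 * pad - kh + 1, ww + 2 * pad - kw + 1
    out = np.zeros((n, oh, ow, cout), dtype=x.dtype)
    for dy in range(kh):
        for dx in range(kw):
            out += xt[:, dy : dy + oh, dx : dx + ow, :] @ w[:, :, dy, dx].T
    return out.transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with symmetric zero padding."""
    out_data = _conv2d_raw(x.data, w.data, pad)
    if b is not None:
        out_data += b.data[None, :, None, None]
    kh, kw = w.data.shape[2:]

    def backward(g: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            oh, ow = g.shape[2:]
            xt = _pad_channels_last(x.data, pad)
            gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
            dw = np.empty_like(w.data)
            for dy in range(kh):
                for dx in range(kw):
                    blk = xt[:, dy : dy + oh, dx : dx + ow, :]
                    dw[:, :, dy, dx] = np.tensordot(
                        gt, blk, axes=([0, 1, 2], [0, 1, 2])
                    )
            w._accumulate(dw)
        if x.requires_grad:
            # gradient w.r.t. input = correlation of the output gradient with
            # the spatially flipped, channel-transposed kernel
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            x._accumulate(_conv2d_raw(g, np.ascontiguousarray(w_flip), kh - 1 - pad))

    prev = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _prev=prev, _backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """x (N, Cin) @ w.T (Cin, Cout) + b."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data += b.data

    def backward(g: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if x.requires_grad:
            x._accumulate(g @ w.data)

    prev = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _prev=prev, _backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) → (N, C) spatial mean (the SE 'squeeze')."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape)
            )

    return Tensor(out_data, _prev=(x,), _backward=backward)


def channel_scale(x: Tensor, s: Tensor) -> Tensor:
    """Rescale feature maps channel-wise: x (N,C,H,W) · s (N,C) (SE 'excite')."""
    out_data = x.data * s.data[:, :, None, None]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * s.data[:, :, None, None])
        if s.requires_grad:
            s._accumulate((g * x.data).sum(axis=(2, 3)))

    return Tensor(out_data, _prev=(x, s), _backward=backward)


def pixel_shuffle(x: Tensor, s: int) -> Tensor:
    """(N, C·s², H, W) → (N, C, H·s, W·s) sub-pixel rearrangement."""
    n, cs2, h, w = x.data.shape
    if cs2 % (s * s):
        raise ValueError(f"channels {cs2} not divisible by scale² = {s * s}")
    c = cs2 // (s * s)
    out_data = (
        x.data.reshape(n, c, s, s, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * s, w * s)
    )

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gi = (
                g.reshape(n, c, h, s, w, s)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, cs2, h, w)
            )
            x._accumulate(gi)

    return Tensor(out_data, _prev=(x,), _backward=backward)


def l1_mean(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference (the L1 pixel loss)."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    diff = a.data - b.data
    out_data = np.abs(diff).mean()
    sign = np.sign(diff) / diff.size

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * sign)
        if b.requires_grad:
            b._accumulate(-g * sign)

    return Tensor(out_data, _prev=(a, b), _backward=backward)
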