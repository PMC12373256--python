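"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its networks on CPU with a small, self-contained tape-based
engine: a :class:`Tensor` wraps a numpy array, records its parents and a
backward closure, and :meth:`Tensor.backward` walks the graph in reverse
topological order accumulating gradients.  Only the operations the
segmentation network needs are implemented (elementwise arithmetic,
reductions, shape ops, a two-operand einsum, softmax, 2D convolution,
2×2 max pooling and gather/scatter primitives used by bilinear sampling).

Gradients are plain numpy arrays stored on ``Tensor.grad``; broadcasting in
forward ops is undone with :func:`_unbroadcast` in the corresponding backward.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "einsum",
    "softmax",
    "conv2d",
    "maxpool2x2",
    "take",
    "gather2d",
    "relu",
    "sigmoid",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(p for p in parents if p.requires_grad) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            # copy: closures may hand us views of shared arrays
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        visited: set[int] = set()
        work: list[tuple[Tensor, bool]] = [(self, False)]
        # iterative DFS post-order
        while work:
            node, processed = work.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            work.append((node, True))
            work.extend((p, False) for p in node._parents)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=_guard(bw, self, other))

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, p: float):
        def bw(g, a=self):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor(self.data ** p, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- elementwise functions ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a._accumulate(g * o)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g, a=self):
            a._accumulate(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sin(self):
        def bw(g, a=self):
            a._accumulate(g * np.cos(a.data))

        return Tensor(np.sin(self.data), parents=(self,), backward=bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a._accumulate(g.reshape(a.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, a=self):
            a._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g, a=self):
            gx = np.zeros_like(a.data)
            np.add.at(gx, idx, g)
            a._accumulate(gx)

        return Tensor(self.data[idx], parents=(self,), backward=bw)


def _guard(bw, *tensors):
    if not any(t.requires_grad for t in tensors):
        return None
    return bw


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype if dtype is not None else None)
    if arr.dtype.kind not in "fc":
        arr = arr.astype(float if dtype is None else dtype)
    return Tensor(arr)


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g, a=x, m=mask):
        a._accumulate(g * m)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g, a=x, o=out_data):
        a._accumulate(g * o * (1.0 - o))

    return Tensor(out_data, parents=(x,), backward=bw)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with automatic differentiation.

    Restricted to specs where every index of each operand appears in the
    output or in the other operand (no internal traces), which covers all
    uses in the attention layers.
    """
    a = as_tensor(a)
    b = as_tensor(b)
    lhs, out_sub = spec.replace(" ", "").split("->")
    sa, sb = lhs.split(",")
    for sub, other in ((sa, sb), (sb, sa)):
        if len(set(sub)) != len(sub):
            raise ValueError(f"einsum spec {spec!r}: repeated index within one operand")
        for ch in sub:
            if ch not in out_sub and ch not in other:
                raise ValueError(f"einsum spec {spec!r}: index {ch!r} untraceable in backward")
    out_data = np.einsum(spec, a.data, b.data, optimize=True)

    def bw(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out_sub},{sb}->{sa}", g, b.data, optimize=True))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out_sub},{sa}->{sb}", g, a.data, optimize=True))

    return Tensor(out_data, parents=(a, b), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-subtracted logits)."""
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g, a=x, pp=p):
        dot = (g * pp).sum(axis=axis, keepdims=True)
        a._accumulate(pp * (g - dot))

    return Tensor(p, parents=(x,), backward=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2D cross-correlation (stride 1) of NCHW input with OIHW weights."""
    B, Ci, H, W = x.shape
    Co, Ci2, kh, kw = w.shape
    if Ci != Ci2:
        raise ValueError(f"conv2d channel mismatch: input {Ci} vs weight {Ci2}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,Ci,Ho,Wo,kh,kw
    out_data = np.einsum("bcijkl,ockl->boij", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    Ho, Wo = out_data.shape[2:]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("boij,bcijkl->ockl", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(kh):
                for l in range(kw):
                    gxp[:, :, k:k + Ho, l:l + Wo] += np.einsum(
                        "boij,oc->bcij", g, w.data[:, :, k, l], optimize=True)
            x._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    return Tensor(out_data, parents=parents, backward=bw)


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even spatial size, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g, a=x):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        a._accumulate(
            gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W))

    return Tensor(out_data, parents=(x,), backward=bw)


def _scatter_matrix(indices: np.ndarray, size: int, dtype) -> np.ndarray:
    """Dense (size, M) one-hot transpose so a scatter-add is one matmul."""
    flat = indices.ravel()
    S = np.zeros((size, flat.size), dtype=dtype)
    S[flat, np.arange(flat.size)] = 1.0
    return S


def take(x: Tensor, indices: np.ndarray, axis: int = 0) -> Tensor:
    """Gather along ``axis`` with an integer index array (backward scatter-adds)."""
    indices = np.asarray(indices)
    out_data = np.take(x.data, indices, axis=axis)

    def bw(g, a=x):
        T = a.shape[axis]
        # move the gathered axes to the front and scatter with one matmul
        gm = np.moveaxis(g, tuple(range(axis, axis + indices.ndim)),
                         tuple(range(indices.ndim)))
        rest = gm.shape[indices.ndim:]
        S = _scatter_matrix(indices, T, g.dtype)
        gxm = S @ gm.reshape(indices.size, -1)
        a._accumulate(np.moveaxis(gxm.reshape((T,) + rest), 0, axis))

    return Tensor(out_data, parents=(x,), backward=bw)


def gather2d(x: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """out[..., i, j] = x[..., iy[i, j], ix[i, j]] for x of shape (..., H, W)."""
    lead = x.shape[:-2]
    H, W = x.shape[-2:]
    out_data = x.data[..., iy, ix]

    def bw(g, a=x):
        n = int(np.prod(lead)) if lead else 1
        flat = (iy * W + ix).ravel()
        idx = (np.arange(n)[:, None] * (H * W) + flat[None, :]).ravel()
        gx = np.bincount(idx, weights=g.reshape(n, -1).ravel().astype(np.float64),
                         minlength=n * H * W)
        a._accumulate(gx.reshape(lead + (H, W)).astype(a.dtype))

    return Tensor(out_data, parents=(x,), backward=bw)
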