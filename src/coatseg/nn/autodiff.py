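"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it in a dynamic graph; :meth:`Tensor.backward` walks the graph in reverse
topological order and accumulates gradients into ``.grad``.  Gradients are
accumulated on *every* tensor that requires grad, not only leaves, so
intermediate activations can be inspected (used for class-activation maps).

Only the operations the segmentation network needs are implemented.  All
arithmetic supports numpy broadcasting; gradients are summed back to the
operand's shape.  Dtype follows the wrapped array (float32 in the models,
float64 in gradient-check tests).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, "Tensor"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "retain_grad", "_backward",
                 "_parents")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self.retain_grad = False
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------- basics
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (transformer blocks)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # interior grads are transient unless explicitly retained
                if not node.retain_grad and node is not self:
                    node.grad = None

    # ---------------------------------------------------------- operators
    def __add__(self, other: ArrayLike) -> "Tensor":
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return add(self, mul(other, -1.0))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return add(mul(self, -1.0), other)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return mul(power(self, -1.0), other)

    def __neg__(self) -> "Tensor":
        return mul(self, -1.0)

    def __pow__(self, exponent: float) -> "Tensor":
        return power(self, exponent)

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        return matmul(self, other)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def _bwd(g: np.ndarray, self=self, idx=idx) -> None:
            full = np.zeros_like(self.data)
            if _is_basic_index(idx):
                full[idx] += g  # basic indexing never aliases
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _bwd if self.requires_grad else None
        return out

    # ------------------------------------------------------- reshaping etc
    def reshape(self, *shape: int) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g, s=self: s._accumulate(g.reshape(s.shape))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g, s=self, inv=tuple(inv): s._accumulate(
                g.transpose(inv)
            )
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        return reduce_mean(self, axis, keepdims)

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        return reduce_max(self, axis, keepdims)


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents))


# ----------------------------------------------------------------- arithmetic
def add(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data + b.data, (a, b))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        out._backward = _bwd
    return out


def mul(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data * b.data, (a, b))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        out._backward = _bwd
    return out


def power(a: ArrayLike, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = _make(np.power(a.data, exponent), (a,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            a._accumulate(g * exponent * np.power(a.data, exponent - 1.0))

        out._backward = _bwd
    return out


def exp(a: ArrayLike) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)
    out = _make(e, (a,))
    if out.requires_grad:
        out._backward = lambda g: a._accumulate(g * e)
    return out


def log(a: ArrayLike) -> Tensor:
    a = as_tensor(a)
    out = _make(np.log(a.data), (a,))
    if out.requires_grad:
        out._backward = lambda g: a._accumulate(g / a.data)
    return out


def sqrt(a: ArrayLike) -> Tensor:
    return power(a, 0.5)


def absolute(a: ArrayLike) -> Tensor:
    """|a|, with the subgradient sign(a) at zero (sign(0)=0)."""
    a = as_tensor(a)
    out = _make(np.abs(a.data), (a,))
    if out.requires_grad:
        out._backward = lambda g: a._accumulate(g * np.sign(a.data))
    return out


def relu(a: ArrayLike) -> Tensor:
    a = as_tensor(a)
    out = _make(np.maximum(a.data, 0.0), (a,))
    if out.requires_grad:
        out._backward = lambda g: a._accumulate(g * (a.data > 0))
    return out


def sigmoid(a: ArrayLike) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(s, (a,))
    if out.requires_grad:
        out._backward = lambda g: a._accumulate(g * s * (1.0 - s))
    return out


def matmul(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            if a.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b.data) if a.ndim > 1 else g * b.data
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(np.asarray(ga), a.shape))
            if b.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a.data, g)
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(np.asarray(gb), b.shape))

        out._backward = _bwd
    return out


# ------------------------------------------------------------------ reductions
def reduce_sum(a: ArrayLike, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape))

        out._backward = _bwd
    return out


def reduce_mean(a: ArrayLike, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reduce_max(a: ArrayLike, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)
    out = _make(out_data, (a,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            expanded = out_data
            gg = g
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                expanded = np.expand_dims(out_data, ax)
                gg = np.expand_dims(g, ax)
            mask = (a.data == expanded)
            # split gradient between ties so the adjoint stays consistent
            counts = mask.sum(
                axis=axis if axis is not None else None, keepdims=True
            )
            a._accumulate((mask * gg / counts).astype(a.dtype))

        out._backward = _bwd
    return out


def softmax(a: ArrayLike, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (a,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate((s * (g - dot)).astype(a.dtype))

        out._backward = _bwd
    return out


def log_softmax(a: ArrayLike, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    ls = shifted - lse
    out = _make(ls, (a,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            soft = np.exp(ls)
            a._accumulate((g - soft * g.sum(axis=axis, keepdims=True)).astype(a.dtype))

        out._backward = _bwd
    return out


def normalize(a: ArrayLike, axes, eps: float = 1e-5) -> Tensor:
    """Standardize over ``axes``: (a - mean) / sqrt(var + eps), one fused op.

    The closed-form adjoint dx = (g - mean(g) - xhat*mean(g*xhat)) / sigma
    avoids materializing the long elementwise chain a composite would build;
    batch-norm and layer-norm are thin wrappers around this primitive.
    """
    a = as_tensor(a)
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    sig = np.sqrt(var + eps)
    xhat = (a.data - mu) / sig
    out = _make(xhat, (a,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            gm = g.mean(axis=axes, keepdims=True)
            gx = (g * xhat).mean(axis=axes, keepdims=True)
            a._accumulate((g - gm - xhat * gx) / sig)

        out._backward = _bwd
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def _bwd(g: np.ndarray) -> None:
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _bwd
    return out


# --------------------------------------------------------- spatial primitives
def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return not any(isinstance(i, (np.ndarray, list)) for i in items)


def _gather_patches(xp: np.ndarray, kh, kw, stride, oh, ow) -> np.ndarray:
    n, c = xp.shape[:2]
    patches = np.empty((n, c, kh * kw, oh * ow), dtype=xp.dtype)
    for ki in range(kh):
        for kj in range(kw):
            view = xp[:, :, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride]
            patches[:, :, ki * kw + kj] = view.reshape(n, c, -1)
    return patches


def _scatter_patches(g: np.ndarray, hp, wp, kh, kw, stride, oh, ow) -> np.ndarray:
    n, c = g.shape[:2]
    acc = np.zeros((n, c, hp, wp), dtype=g.dtype)
    for ki in range(kh):
        for kj in range(kw):
            acc[:, :, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride] += (
                g[:, :, ki * kw + kj].reshape(n, c, oh, ow)
            )
    return acc


def im2col(x: Tensor, kh: int, kw: int, stride: int = 1, pad: int = 0) -> Tensor:
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) patch matrix (adjoint: col2im scatter)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    patches = _gather_patches(xp, kh, kw, stride, oh, ow)
    out = _make(patches.reshape(n, c * kh * kw, -1), (x,))
    if out.requires_grad:

        def _bwd(g: np.ndarray) -> None:
            g = g.reshape(n, c, kh * kw, -1)
            acc = _scatter_patches(g, h + 2 * pad, w + 2 * pad, kh, kw, stride,
                                   oh, ow)
            if pad:
                acc = acc[:, :, pad:-pad, pad:-pad]
            x._accumulate(acc)

        out._backward = _bwd
    return out


def col2im(
    cols: Tensor, out_hw: Tuple[int, int], c: int, kh: int, kw: int,
    stride: int = 1, pad: int = 0,
) -> Tensor:
    """Adjoint of :func:`im2col`: scatter (N, C*kh*kw, L) back to (N,C,H,W)."""
    cols = as_tensor(cols)
    h, w = out_hw
    n = cols.shape[0]
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    g = cols.data.reshape(n, c, kh * kw, -1)
    acc = _scatter_patches(g, h + 2 * pad, w + 2 * pad, kh, kw, stride, oh, ow)
    if pad:
        acc = acc[:, :, pad:-pad, pad:-pad]
    out = _make(acc, (cols,))
    if out.requires_grad:

        def _bwd(gr: np.ndarray) -> None:
            gp = np.pad(gr, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else gr
            patches = _gather_patches(gp, kh, kw, stride, oh, ow)
            cols._accumulate(patches.reshape(cols.shape))

        out._backward = _bwd
    return out


def _interp_matrix(in_len: int, out_len: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation operator (align_corners=False)."""
    coords = (np.arange(out_len) + 0.5) * in_len / out_len - 0.5
    lo = np.floor(coords).astype(int)
    frac = coords - lo
    lo0 = np.clip(lo, 0, in_len - 1)
    lo1 = np.clip(lo + 1, 0, in_len - 1)
    mat = np.zeros((out_len, in_len), dtype=dtype)
    np.add.at(mat, (np.arange(out_len), lo0), 1.0 - frac)
    np.add.at(mat, (np.arange(out_len), lo1), frac)
    return mat


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (N,C,H,W) as a separable linear map (its adjoint is
    the transposed map, so the gradient is two small matmuls as well)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    ah = _interp_matrix(h, out_h, x.dtype)   # (OH, H)
    aw = _interp_matrix(w, out_w, x.dtype)   # (OW, W)
    out_data = ah @ (x.data @ aw.T)          # (N, C, OH, OW)
    out = _make(out_data, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(ah.T @ (g @ aw))
    return out
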