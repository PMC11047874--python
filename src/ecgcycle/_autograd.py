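"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape: exactly the operations the signal models in this
package need — broadcasting arithmetic, pointwise nonlinearities, reductions,
dense matmul, concatenation, and strided/dilated 1-D convolution plus its
transpose, the latter two with fused hand-written gradients for speed.

Everything is float32 and seeded numpy, so training trajectories are
bitwise reproducible on a fixed BLAS.
"""
from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._node(out_data, (self,), backward)

    # -- pointwise nonlinearities ---------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._node(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._node(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return Tensor._node(out_data, (self,), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        out_data = np.clip(self.data, lo, hi)
        passed = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            passed &= self.data >= lo
        if hi is not None:
            passed &= self.data <= hi

        def backward(g):
            if self.requires_grad:
                self._accum(g * passed)

        return Tensor._node(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- linear algebra ---------------------------------------------------------
    def matmul(self, other: "Tensor"):
        """2-D matrix product: (N, F) @ (F, O)."""
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._node(out_data, (self, other), backward)

    def __matmul__(self, other):
        return self.matmul(other)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        old_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return Tensor._node(out_data, (self,), backward)

    # -- autodiff driver --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or node._backward is None:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._node(out_data, tuple(tensors), backward)


# -- 1-D convolutions ----------------------------------------------------------


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: tuple[int, int] = (0, 0),
    dilation: int = 1,
) -> Tensor:
    """Batched 1-D convolution (cross-correlation).

    x: (N, C_in, L); w: (C_out, C_in, K); padding is (left, right).
    """
    xd, wd = x.data, w.data
    n, c_in, length = xd.shape
    c_out, c_in_w, k = wd.shape
    if c_in_w != c_in:
        raise ValueError(f"weight expects {c_in_w} input channels, got {c_in}")
    pl, pr = padding
    xp = np.pad(xd, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else xd
    lp = length + pl + pr
    span = dilation * (k - 1) + 1
    if lp < span:
        raise ValueError(f"input length {length} shorter than kernel span {span}")
    l_out = (lp - span) // stride + 1
    idx = stride * np.arange(l_out)[None, :] + dilation * np.arange(k)[:, None]
    cols = xp[:, :, idx].reshape(n, c_in * k, l_out)
    w2 = wd.reshape(c_out, c_in * k)
    out_data = np.matmul(w2, cols)
    if b is not None:
        out_data = out_data + b.data.reshape(1, c_out, 1)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.matmul(
                g.transpose(1, 0, 2).reshape(c_out, n * l_out),
                cols.transpose(0, 2, 1).reshape(n * l_out, c_in * k),
            )
            w._accum(gw.reshape(c_out, c_in, k))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g).reshape(n, c_in, k, l_out)
            dxp = np.zeros((n, c_in, lp), dtype=DTYPE)
            for kk in range(k):
                s = kk * dilation
                dxp[:, :, s : s + stride * l_out : stride] += dcols[:, :, kk, :]
            x._accum(dxp[:, :, pl : lp - pr] if (pl or pr) else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out_data, parents, backward)


def conv_transpose1d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Batched 1-D transposed convolution.

    x: (N, C_in, L); w: (C_in, C_out, K); output length (L-1)*stride + K - 2*padding.
    """
    xd, wd = x.data, w.data
    n, c_in, length = xd.shape
    c_in_w, c_out, k = wd.shape
    if c_in_w != c_in:
        raise ValueError(f"weight expects {c_in_w} input channels, got {c_in}")
    w2 = wd.reshape(c_in, c_out * k)
    cols = np.matmul(w2.T, xd).reshape(n, c_out, k, length)
    l_full = (length - 1) * stride + k
    ypad = np.zeros((n, c_out, l_full), dtype=DTYPE)
    for kk in range(k):
        ypad[:, :, kk : kk + stride * length : stride] += cols[:, :, kk, :]
    out_data = ypad[:, :, padding : l_full - padding] if padding else ypad
    if out_data.shape[2] <= 0:
        raise ValueError("padding exceeds transposed-convolution output length")
    if b is not None:
        out_data = out_data + b.data.reshape(1, c_out, 1)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        gpad = np.pad(g, ((0, 0), (0, 0), (padding, padding))) if padding else g
        dcols = np.empty((n, c_out, k, length), dtype=DTYPE)
        for kk in range(k):
            dcols[:, :, kk, :] = gpad[:, :, kk : kk + stride * length : stride]
        dcols2 = dcols.reshape(n, c_out * k, length)
        if x.requires_grad:
            x._accum(np.matmul(w2, dcols2))
        if w.requires_grad:
            gw = np.matmul(
                xd.transpose(1, 0, 2).reshape(c_in, n * length),
                dcols2.transpose(0, 2, 1).reshape(n * length, c_out * k),
            )
            w._accum(gw.reshape(c_in, c_out, k))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out_data, parents, backward)
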