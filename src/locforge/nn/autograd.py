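"""A minimal reverse-mode automatic differentiation engine on numpy.

Just enough machinery to train the hybrid localization network: a
:class:`Tensor` wrapping an ndarray, elementwise arithmetic with
broadcasting, matmul, the activations used by the model, reductions,
shape ops, and dedicated strided convolution / max-pooling primitives.
Gradients are accumulated by a topological-order backward sweep; all
primitives are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` along broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(parents)
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        b = self._lift(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data**exponent

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return self._node(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                gb = a.data.swapaxes(-1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._node(a.data @ b.data, (a, b), backward)

    # -- nonlinearities ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        a = self

        def backward(g):
            a._accumulate(g * out_data)

        return self._node(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return self._node(np.log(a.data), (a,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        a = self

        def backward(g):
            a._accumulate(g * (1.0 - out_data**2))

        return self._node(out_data, (a,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        a = self

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return self._node(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return self._node(a.data * mask, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient flows only where the input is inside [lo, hi]."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            a._accumulate(g * mask)

        return self._node(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions and shape ops ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        a = self

        def backward(g):
            a._accumulate(g.reshape(a.shape))

        return self._node(a.data.reshape(*shape), (a,), backward)

    def __getitem__(self, key):
        a = self

        fancy = isinstance(key, (np.ndarray, list)) or (
            isinstance(key, tuple) and any(isinstance(k, (np.ndarray, list)) for k in key)
        )

        def backward(g):
            full = np.zeros_like(a.data)
            if fancy:  # repeated indices must accumulate
                np.add.at(full, key, g)
            else:
                full[key] += g
            a._accumulate(full)

        return self._node(a.data[key], (a,), backward)

    def flip(self, axis: int):
        a = self

        def backward(g):
            a._accumulate(np.flip(g, axis=axis))

        return self._node(np.flip(a.data, axis=axis), (a,), backward)

    # -- convolution primitives -------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int):
        """Valid (unpadded) strided 2D convolution.

        ``self``: (N, C, H, W); ``weight``: (F, C, kh, kw); ``bias``: (F,).
        """
        x, w, b = self, weight, bias
        N, C, H, W = x.shape
        F, _, kh, kw = w.shape
        oh = (H - kh) // stride + 1
        ow = (W - kw) // stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
        windows = windows[:, :, ::stride, ::stride]  # N,C,oh,ow,kh,kw
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(N * oh * ow, C * kh * kw)
        wmat = w.data.reshape(F, -1)
        out_data = (cols @ wmat.T + b.data).reshape(N, oh, ow, F).transpose(0, 3, 1, 2)

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(N * oh * ow, F)
            if w.requires_grad:
                w._accumulate((gmat.T @ cols).reshape(w.shape))
            if b.requires_grad:
                b._accumulate(gmat.sum(axis=0))
            if x.requires_grad:
                gcols = (gmat @ wmat).reshape(N, oh, ow, C, kh, kw)
                gx = np.zeros_like(x.data)
                for i in range(oh):
                    for j in range(ow):
                        gx[:, :, i * stride : i * stride + kh, j * stride : j * stride + kw] += (
                            gcols[:, i, j]
                        )
                x._accumulate(gx)

        return self._node(out_data, (x, w, b), backward)

    def maxpool2d(self, pool: int, stride: int):
        """Valid strided 2D max pooling over (N, C, H, W)."""
        x = self
        N, C, H, W = x.shape
        oh = (H - pool) // stride + 1
        ow = (W - pool) // stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(x.data, (pool, pool), axis=(2, 3))
        windows = windows[:, :, ::stride, ::stride]  # N,C,oh,ow,p,p
        flat = windows.reshape(N, C, oh, ow, pool * pool)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gx = np.zeros_like(x.data)
            pi, pj = np.divmod(arg, pool)
            n_idx, c_idx, i_idx, j_idx = np.indices((N, C, oh, ow))
            np.add.at(
                gx,
                (n_idx, c_idx, i_idx * stride + pi, j_idx * stride + pj),
                g,
            )
            x._accumulate(gx)

        return self._node(out_data, (x,), backward)

    # -- backward machinery -------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._node(out_data, tensors, backward)
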