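"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the model needs: broadcasting
arithmetic, matmul (with leading batch dimensions), exp/log/power, ReLU,
reductions, reshape/transpose and concatenation.  Convolution and pooling
are built on top of these in :mod:`msa3d.nn.layers` as custom primitives.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the tape in reverse topological order.  The engine is
dtype-preserving: float32 throughout the model, float64 in tests where
finite-difference checks need the headroom.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "log_softmax", "softmax", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    """Context manager disabling tape construction (inference mode)."""

    enabled = False

    def __enter__(self):
        self._prev = _NoGrad.enabled
        _NoGrad.enabled = True

    def __exit__(self, *exc):
        _NoGrad.enabled = self._prev


def no_grad() -> _NoGrad:
    return _NoGrad()


class Tensor:
    """A NumPy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "retains_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad.enabled
        self.retains_grad = False
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helper for op results -------------------------------
    @staticmethod
    def _result(data, parents, backward):
        req = any(p.requires_grad for p in parents) and not _NoGrad.enabled
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def retain_grad(self) -> "Tensor":
        self.retains_grad = True
        return self

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # weak promotion, keeps dtype
            a, c = self, other
            return Tensor._result(a.data + c, (a,), lambda g: (g,))
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._result(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a, c = self, other
            return Tensor._result(a.data * c, (a,), lambda g: (g * c,))
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.shape),
                    _unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g / b.data, a.shape),
                    _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            return (g * e * np.power(a.data, e - 1.0),)

        return Tensor._result(np.power(a.data, e), (a,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
                gb = a.data.T @ g if a.data.ndim == 2 else (a.data * g[..., None]).sum(
                    tuple(range(a.data.ndim - 1)))
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._result(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._result(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._result(np.log(a.data), (a,), lambda g: (g / a.data,))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._result(np.where(mask, a.data, 0.0), (a,),
                              lambda g: (np.where(mask, g, 0.0),))

    def sqrt(self):
        return self ** 0.5

    # -- reductions and shape ops -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(ax % a.data.ndim for ax in axes)
                for ax in sorted(axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, a.shape).astype(a.dtype, copy=False),)

        return Tensor._result(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._result(a.data.reshape(shape), (a,),
                              lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._result(a.data.transpose(axes), (a,),
                              lambda g: (g.transpose(inv),))

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._result(np.swapaxes(a.data, ax1, ax2), (a,),
                              lambda g: (np.swapaxes(g, ax1, ax2),))

    def __getitem__(self, key):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor._result(a.data[key], (a,), backward)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None or node.retains_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for p, pg in zip(node._prev, node._backward(g)):
                    if not p.requires_grad or pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg


class Parameter(Tensor):
    """A trainable tensor; ``decay`` marks it for weight-decay regularisation."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(np.asarray(data), requires_grad=True)
        self.decay = decay


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient support."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tensors, backward)


def softmax(t: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-subtraction)."""
    shift = Tensor(t.data.max(axis=axis, keepdims=True))  # constant: no gradient
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    z = t - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
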