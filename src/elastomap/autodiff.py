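"""Minimal vectorized reverse-mode automatic differentiation.

A small tape-based engine over NumPy arrays, sufficient for training the
physics-informed networks in :mod:`elastomap.pinn`: elementwise arithmetic,
matrix products, a handful of transcendental functions, reductions, and
column slicing.  Gradients are accumulated by a reverse topological sweep.

The module-level math helpers (:func:`log`, :func:`exp`, ...) dispatch on
their argument type, so code written against them (e.g. the constitutive
stress formulas) runs unchanged on plain ``ndarray`` inputs and on
:class:`Tensor` nodes inside a training graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "astensor",
    "exp",
    "log",
    "sin",
    "cos",
    "sqrt",
    "sigmoid",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a NumPy array."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value)
        self._parents = parents
        self._backward = backward
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.value + other.value, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.value.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def backward(g):
            self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        other = astensor(other)
        out = Tensor(self.value - other.value, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.value.shape))

        out._backward = backward
        return out

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.value * other.value, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.value.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.value / other.value, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * out.value / other.value, other.value.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.value**exponent, (self,))

        def backward(g):
            self._accumulate(g * exponent * self.value ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.value @ other.value, (self, other))
        batched = self.value.ndim == 3 and other.value.ndim == 2

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.value.T)
            if other.requires_grad:
                if batched:
                    other._accumulate(np.tensordot(self.value, g, axes=([0, 1], [0, 1])))
                else:
                    other._accumulate(self.value.T @ g)

        out._backward = backward
        return out

    def __getitem__(self, index):
        out = Tensor(self.value[index], (self,))
        basic = isinstance(index, (int, slice)) or (
            isinstance(index, tuple)
            and all(isinstance(i, (int, slice)) for i in index)
        )

        def backward(g):
            full = np.zeros_like(self.value)
            if basic:  # basic slices address disjoint entries
                full[index] = g
            else:
                np.add.at(full, index, g)
            self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self):
        out = Tensor(self.value.sum(), (self,))

        def backward(g):
            self._accumulate(np.broadcast_to(g, self.value.shape))

        out._backward = backward
        return out

    def mean(self):
        n = self.value.size
        out = Tensor(self.value.mean(), (self,))

        def backward(g):
            self._accumulate(np.broadcast_to(g / n, self.value.shape))

        out._backward = backward
        return out

    # -- autodiff driver -----------------------------------------------------
    def _accumulate(self, g):
        # grads are never mutated in place, so storing a reference is safe
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self):
        """Reverse sweep seeding d(self)/d(self) = 1; ``self`` must be scalar."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(1.0, dtype=self.value.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # free intermediate grads; leaves keep theirs
                node.grad = None


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(np.asarray(value), requires_grad=True)


def _unary(x, fn, dfn, method):
    if isinstance(x, Tensor):
        val = fn(x.value)
        out = Tensor(val, (x,))

        def backward(g):
            x._accumulate(g * dfn(x.value, val))

        out._backward = backward
        return out
    if isinstance(x, (np.ndarray, np.generic, float, int)):
        return fn(np.asarray(x))
    # duck-typed fallback (e.g. dual numbers)
    return getattr(x, method)()


def exp(x):
    return _unary(x, np.exp, lambda v, o: o, "exp")


def log(x):
    return _unary(x, np.log, lambda v, o: 1.0 / v, "log")


def sin(x):
    return _unary(x, np.sin, lambda v, o: np.cos(v), "sin")


def cos(x):
    return _unary(x, np.cos, lambda v, o: -np.sin(v), "cos")


def sqrt(x):
    return _unary(x, np.sqrt, lambda v, o: 0.5 / o, "sqrt")


def _sigmoid_np(v):
    # exp overflow saturates harmlessly to 0/1
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-v))


def sigmoid(x):
    if isinstance(x, Tensor):
        val = _sigmoid_np(x.value)
        out = Tensor(val, (x,))

        def backward(g):
            x._accumulate(g * val * (1.0 - val))

        out._backward = backward
        return out
    return _sigmoid_np(np.asarray(x, dtype=float))


try:  # single-pass fused kernels; NumPy fallbacks below keep results identical
    from numba import njit

    @njit(fastmath=False)
    def _swish_fwd_kernel(z, zg):
        n, w = z.shape
        s = np.empty_like(z)
        s1 = np.empty_like(z)
        sg = np.empty_like(zg)
        for i in range(n):
            for j in range(w):
                sig = 1.0 / (1.0 + np.exp(-z[i, j]))
                sv = z[i, j] * sig
                s[i, j] = sv
                s1v = sig + sv * (1.0 - sig)
                s1[i, j] = s1v
                sg[i, j] = s1v * zg[i, j]
                sg[n + i, j] = s1v * zg[n + i, j]
        return s, s1, sg

    @njit(fastmath=False)
    def _swish_bwd_grad_kernel(g, z, zg, s1):
        n, w = z.shape
        dzg = np.empty_like(zg)
        dz = np.empty_like(z)
        for i in range(n):
            for j in range(w):
                s1v = s1[i, j]
                dzg[i, j] = s1v * g[i, j]
                dzg[n + i, j] = s1v * g[n + i, j]
                sig = 1.0 / (1.0 + np.exp(-z[i, j]))
                s2 = sig * (1.0 - sig) * (2.0 + z[i, j] * (1.0 - 2.0 * sig))
                dz[i, j] = s2 * (g[i, j] * zg[i, j] + g[n + i, j] * zg[n + i, j])
        return dzg, dz

except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _swish_fwd_kernel = None
    _swish_bwd_grad_kernel = None


def swish_channels(z, zg):
    """Fused Swish activation for a value channel and stacked derivative rows.

    Given pre-activations ``z`` (N, W) and the row-stacked spatial-derivative
    channels ``zg`` (2N, W), returns ``(swish(z), swish'(z) * zg)`` as two
    tensors in a single fused tape node pair — the chain rule through both
    outputs is applied analytically in the backward closures.
    """
    z = astensor(z)
    zg = astensor(zg)
    zv, zgv = z.value, zg.value
    n = zv.shape[0]
    if _swish_fwd_kernel is not None:
        s, s1, sgv = _swish_fwd_kernel(zv, zgv)
        sig = None
    else:
        with np.errstate(over="ignore"):
            sig = 1.0 / (1.0 + np.exp(-zv))
        s = zv * sig
        s1 = sig + s * (1.0 - sig)
        sgv = (s1 * zgv.reshape(2, n, -1)).reshape(zgv.shape)
    out = Tensor(s, (z,))
    outg = Tensor(sgv, (z, zg))

    def back_value(g):
        z._accumulate(g * s1)

    def back_grad(g):
        if _swish_bwd_grad_kernel is not None:
            dzg, dz = _swish_bwd_grad_kernel(
                np.ascontiguousarray(g), zv, zgv, s1
            )
            if zg.requires_grad:
                zg._accumulate(dzg)
            if z.requires_grad:
                z._accumulate(dz)
            return
        gr3 = g.reshape(2, n, -1)
        if zg.requires_grad:
            zg._accumulate((s1 * gr3).reshape(g.shape))
        if z.requires_grad:
            s2 = (sig * (1.0 - sig)) * (2.0 + zv * (1.0 - 2.0 * sig))
            z._accumulate(s2 * (gr3 * zgv.reshape(2, n, -1)).sum(axis=0))

    out._backward = back_value
    outg._backward = back_grad
    return out, outg


def concat(tensors, axis=1):
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [astensor(t) for t in tensors]
    values = [t.value for t in tensors]
    out = Tensor(np.concatenate(values, axis=axis), tuple(tensors))
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out
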