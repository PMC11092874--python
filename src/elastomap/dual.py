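"""First-order dual numbers carrying spatial derivatives.

A :class:`Dual` bundles a quantity with its x- and y-derivatives.  The three
slots may be NumPy arrays or autodiff :class:`~elastomap.autodiff.Tensor`
nodes; arithmetic applies the chain rule slot-wise, so running the generic
constitutive formulas on duals yields the spatial divergence of the stress
while remaining differentiable with respect to network weights.
"""

from __future__ import annotations

from . import autodiff as ad

__all__ = ["Dual"]


def _as_dual(x):
    return x if isinstance(x, Dual) else Dual(x, 0.0, 0.0)


class Dual:
    __slots__ = ("val", "dx", "dy")

    def __init__(self, val, dx, dy):
        self.val = val
        self.dx = dx
        self.dy = dy

    def __repr__(self):
        return f"Dual({self.val!r})"

    def __add__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val + other.val, self.dx + other.dx, self.dy + other.dy)
        return Dual(self.val + other, self.dx, self.dy)

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.dx, -self.dy)

    def __sub__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val - other.val, self.dx - other.dx, self.dy - other.dy)
        return Dual(self.val - other, self.dx, self.dy)

    def __rsub__(self, other):
        return Dual(other - self.val, -self.dx, -self.dy)

    def __mul__(self, other):
        if isinstance(other, Dual):
            return Dual(
                self.val * other.val,
                self.dx * other.val + self.val * other.dx,
                self.dy * other.val + self.val * other.dy,
            )
        return Dual(self.val * other, self.dx * other, self.dy * other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Dual):
            inv = 1.0 / other.val
            q = self.val * inv
            return Dual(
                q,
                (self.dx - q * other.dx) * inv,
                (self.dy - q * other.dy) * inv,
            )
        return Dual(self.val / other, self.dx / other, self.dy / other)

    def __rtruediv__(self, other):
        return _as_dual(other) / self

    def __pow__(self, exponent):
        val = self.val**exponent
        der = exponent * self.val ** (exponent - 1)
        return Dual(val, der * self.dx, der * self.dy)

    def log(self):
        inv = 1.0 / self.val
        return Dual(ad.log(self.val), inv * self.dx, inv * self.dy)

    def exp(self):
        val = ad.exp(self.val)
        return Dual(val, val * self.dx, val * self.dy)
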