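"""PINN architectures: Fourier features, FCNN topologies, output transforms.

Twenty architecture variants are available: five fully connected topologies
(I–V, differing in how displacement, modulus and stress outputs share
layers) crossed with four input/constraint variants (A: hard boundary
constraint, B: plain, C: Fourier features + hard constraint, D: Fourier
features).  Networks use the Swish activation and Glorot-normal
initialization under a run seed.

Every forward pass propagates first (and optionally second) spatial
derivatives of all outputs alongside their values, closed-form layer by
layer, so PDE residuals and strain losses need no nested automatic
differentiation: the whole propagation is itself recorded on the reverse-mode
tape of :mod:`elastomap.autodiff` and is differentiable with respect to the
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, astensor, parameter, sigmoid, swish_channels

__all__ = [
    "ArchitectureSpec",
    "Bundle",
    "fourier_features",
    "input_features",
    "MLP",
    "FCNN",
    "n_parameters",
    "OutputTransforms",
    "apply_output_transforms",
]

_FCNN_NAMES = ("I", "II", "III", "IV", "V")
# letter -> (fourier, hard_bc)
_VARIANT_LETTERS = {
    "A": (False, True),
    "B": (False, False),
    "C": (True, True),
    "D": (True, False),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """One of the 20 PINN variants, e.g. ``ArchitectureSpec.from_code("IIB")``."""

    fcnn: str = "II"
    fourier: bool = False
    hard_bc: bool = False
    activation: str = "swish"
    seed: int = 0

    def __post_init__(self):
        if self.fcnn not in _FCNN_NAMES:
            raise ValueError(f"unknown FCNN topology {self.fcnn!r}")
        if self.activation != "swish":
            raise ValueError("only the swish activation is supported")

    @classmethod
    def from_code(cls, code: str, seed: int = 0) -> "ArchitectureSpec":
        """Parse codes like ``"IIB"`` or ``"IVC"`` (FCNN numeral + variant letter)."""
        code = code.strip().upper()
        letter = code[-1:]
        fcnn = code[:-1]
        if letter not in _VARIANT_LETTERS or fcnn not in _FCNN_NAMES:
            raise ValueError(f"invalid architecture code {code!r}")
        fourier, hard_bc = _VARIANT_LETTERS[letter]
        return cls(fcnn=fcnn, fourier=fourier, hard_bc=hard_bc, seed=seed)

    @property
    def code(self) -> str:
        letter = next(
            k for k, v in _VARIANT_LETTERS.items() if v == (self.fourier, self.hard_bc)
        )
        return self.fcnn + letter

    @property
    def has_stress_outputs(self) -> bool:
        return self.fcnn in ("I", "II")


# ---------------------------------------------------------------------------
# Input features
# ---------------------------------------------------------------------------


def fourier_features(x, y) -> np.ndarray:
    """Feature map ``[x, y, sin(i pi x), sin(i pi y)] for i = 1..5`` (N, 12)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    i = np.arange(1, 6)
    return np.concatenate(
        [x[:, None], y[:, None], np.sin(np.pi * i * x[:, None]), np.sin(np.pi * i * y[:, None])],
        axis=1,
    )


class Bundle:
    """A quantity and its spatial derivatives (arrays or Tensors).

    First derivatives may be held either explicitly (``dx``/``dy``) or as a
    single row-stacked tensor ``dg`` with the x-channel in the first half of
    axis 0 and the y-channel in the second — the fast path used inside MLP
    layers, where both channels share every weight multiply as one GEMM.
    Accessing ``.dx``/``.dy`` slices the stack lazily (cached).
    """

    __slots__ = ("val", "dg", "_dx", "_dy", "dxx", "dxy", "dyy")

    def __init__(self, val, dx=None, dy=None, dxx=None, dxy=None, dyy=None, dg=None):
        self.val = val
        self.dg = dg
        self._dx = dx
        self._dy = dy
        self.dxx = dxx
        self.dxy = dxy
        self.dyy = dyy

    @property
    def dx(self):
        if self._dx is None and self.dg is not None:
            self._dx = self.dg[: self.val.shape[0]]
        return self._dx

    @property
    def dy(self):
        if self._dy is None and self.dg is not None:
            self._dy = self.dg[self.val.shape[0] :]
        return self._dy

    def column(self, i: int) -> "Bundle":
        out = Bundle(self.val[:, i])
        if self.dg is not None:
            out.dg = self.dg[:, i]
        else:
            if self._dx is not None:
                out._dx = self._dx[:, i]
            if self._dy is not None:
                out._dy = self._dy[:, i]
        for f in ("dxx", "dxy", "dyy"):
            t = getattr(self, f)
            if t is not None:
                setattr(out, f, t[:, i])
        return out


def input_features(
    points: np.ndarray, fourier: bool, order: int = 1, dtype=np.float64
) -> Bundle:
    """Constant input bundle for a collocation set (values + derivatives)."""
    points = np.asarray(points, dtype=float)
    x, y = points[:, 0], points[:, 1]
    n = len(points)
    if not fourier:
        val = points.copy()
        dx = np.tile([1.0, 0.0], (n, 1))
        dy = np.tile([0.0, 1.0], (n, 1))
        zero = np.zeros((n, 2))
        dxx = dxy = dyy = zero
    else:
        i = np.arange(1, 6)
        w = np.pi * i
        sx, cx = np.sin(w * x[:, None]), np.cos(w * x[:, None])
        sy, cy = np.sin(w * y[:, None]), np.cos(w * y[:, None])
        zeros5 = np.zeros((n, 5))
        col = lambda v: np.full((n, 1), v)
        val = np.concatenate([x[:, None], y[:, None], sx, sy], axis=1)
        dx = np.concatenate([col(1.0), col(0.0), w * cx, zeros5], axis=1)
        dy = np.concatenate([col(0.0), col(1.0), zeros5, w * cy], axis=1)
        dxx = np.concatenate([col(0.0), col(0.0), -(w**2) * sx, zeros5], axis=1)
        dyy = np.concatenate([col(0.0), col(0.0), zeros5, -(w**2) * sy], axis=1)
        dxy = np.zeros_like(val)
    cast = lambda a: astensor(np.ascontiguousarray(a, dtype=dtype))
    if order < 2:
        return Bundle(cast(val), dg=cast(np.vstack([dx, dy])))
    return Bundle(cast(val), cast(dx), cast(dy), cast(dxx), cast(dxy), cast(dyy))


# ---------------------------------------------------------------------------
# Multilayer perceptron with derivative propagation
# ---------------------------------------------------------------------------


class MLP:
    """Fully connected net with Swish hidden layers and a linear output.

    With ``terminal_activation=True`` the final layer is also activated
    (used for shared trunks whose output feeds further branches).
    """

    def __init__(self, sizes, rng: np.random.Generator, terminal_activation=False, dtype=np.float64):
        self.sizes = list(sizes)
        self.terminal_activation = terminal_activation
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(
                parameter(rng.normal(0.0, scale, (fan_in, fan_out)).astype(dtype))
            )
            self.biases.append(parameter(np.zeros(fan_out, dtype=dtype)))

    @property
    def parameters(self):
        return self.weights + self.biases

    def forward(self, b: Bundle, order: int = 1) -> Bundle:
        if order >= 2:
            return self._forward_second(b)
        a, ag = b.val, b.dg  # ag row-stacks the (d/dx, d/dy) channels: (2N, d)
        n_layers = len(self.weights)
        for idx, (W, bias) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + bias
            zg = ag @ W
            if idx == n_layers - 1 and not self.terminal_activation:
                a, ag = z, zg
                break
            a, ag = swish_channels(z, zg)
        return Bundle(a, dg=ag)

    def _forward_second(self, b: Bundle) -> Bundle:
        a, ax, ay = b.val, b.dx, b.dy
        axx, axy, ayy = b.dxx, b.dxy, b.dyy
        n_layers = len(self.weights)
        for idx, (W, bias) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + bias
            zx, zy = ax @ W, ay @ W
            zxx, zxy, zyy = axx @ W, axy @ W, ayy @ W
            if idx == n_layers - 1 and not self.terminal_activation:
                a, ax, ay = z, zx, zy
                axx, axy, ayy = zxx, zxy, zyy
                break
            # swish: s = z*sig, s' = sig + s(1-sig), s'' = sig(1-sig)(2 + z(1-2 sig))
            sig = sigmoid(z)
            one_minus = 1.0 - sig
            s = z * sig
            s1 = sig + s * one_minus
            a = s
            ax, ay = s1 * zx, s1 * zy
            s2 = (sig * one_minus) * (2.0 + z * (1.0 - 2.0 * sig))
            axx = s2 * (zx * zx) + s1 * zxx
            axy = s2 * (zx * zy) + s1 * zxy
            ayy = s2 * (zy * zy) + s1 * zyy
        return Bundle(a, ax, ay, axx, axy, ayy)


# ---------------------------------------------------------------------------
# FCNN topologies
# ---------------------------------------------------------------------------


class FCNN:
    """One of the five output-branching topologies.

    Published layer plans (input dim ``d`` is 2, or 12 with Fourier
    features):

    * I  — displacement: shared ``d->50->50`` trunk then two ``50x2`` branches
      of width 50, one per component; stress/modulus: one ``d->75 (x5) -> 5``
      net emitting ``(NE, NP11, NP12, NP21, NP22)``.
    * II — two independent 5x75 nets: one -> ``(Nux, Nuy)``, one ->
      ``(NE, NP..)``.
    * III — shared ``d->25->25`` trunk, then three 3x25 branches ->
      ``Nux / Nuy / NE``.
    * IV — three independent 5x25 nets.
    * V  — one shared 5x50 net -> ``(Nux, Nuy, NE)``.
    """

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator, dtype=np.float64):
        self.spec = spec
        d = 12 if spec.fourier else 2
        mk = lambda sizes, term=False: MLP(sizes, rng, terminal_activation=term, dtype=dtype)
        v = spec.fcnn
        if v == "I":
            self.nets = {
                "trunk_u": mk([d, 50, 50], term=True),
                "ux": mk([50, 50, 50, 1]),
                "uy": mk([50, 50, 50, 1]),
                "EP": mk([d, 75, 75, 75, 75, 75, 5]),
            }
        elif v == "II":
            self.nets = {
                "u": mk([d, 75, 75, 75, 75, 75, 2]),
                "EP": mk([d, 75, 75, 75, 75, 75, 5]),
            }
        elif v == "III":
            self.nets = {
                "trunk": mk([d, 25, 25], term=True),
                "ux": mk([25, 25, 25, 25, 1]),
                "uy": mk([25, 25, 25, 25, 1]),
                "E": mk([25, 25, 25, 25, 1]),
            }
        elif v == "IV":
            self.nets = {
                "ux": mk([d, 25, 25, 25, 25, 25, 1]),
                "uy": mk([d, 25, 25, 25, 25, 25, 1]),
                "E": mk([d, 25, 25, 25, 25, 25, 1]),
            }
        elif v == "V":
            self.nets = {"uE": mk([d, 50, 50, 50, 50, 50, 3])}
        else:  # pragma: no cover - guarded by ArchitectureSpec
            raise ValueError(v)

    @property
    def parameters(self):
        params = []
        for net in self.nets.values():
            params.extend(net.parameters)
        return params

    def evaluate(self, feats: Bundle, order: int = 1) -> dict:
        """Raw network outputs as scalar bundles.

        Returns a dict with keys ``ux``, ``uy``, ``E`` and, for topologies
        I/II, ``P`` (a list of four bundles ordered P11, P12, P21, P22).
        """
        v = self.spec.fcnn
        out: dict = {}
        if v == "I":
            trunk = self.nets["trunk_u"].forward(feats, order)
            out["ux"] = self.nets["ux"].forward(trunk, order).column(0)
            out["uy"] = self.nets["uy"].forward(trunk, order).column(0)
            ep = self.nets["EP"].forward(feats, order)
            out["E"] = ep.column(0)
            out["P"] = [ep.column(i) for i in range(1, 5)]
        elif v == "II":
            u = self.nets["u"].forward(feats, order)
            out["ux"], out["uy"] = u.column(0), u.column(1)
            ep = self.nets["EP"].forward(feats, order)
            out["E"] = ep.column(0)
            out["P"] = [ep.column(i) for i in range(1, 5)]
        elif v == "III":
            trunk = self.nets["trunk"].forward(feats, order)
            out["ux"] = self.nets["ux"].forward(trunk, order).column(0)
            out["uy"] = self.nets["uy"].forward(trunk, order).column(0)
            out["E"] = self.nets["E"].forward(trunk, order).column(0)
        elif v == "IV":
            for key in ("ux", "uy", "E"):
                out[key] = self.nets[key].forward(feats, order).column(0)
        else:  # V
            ue = self.nets["uE"].forward(feats, order)
            out["ux"], out["uy"], out["E"] = (ue.column(i) for i in range(3))
        return out


def n_parameters(fcnn: FCNN) -> int:
    """Total trainable scalar count (weights + biases)."""
    return int(sum(p.value.size for p in fcnn.parameters))


# ---------------------------------------------------------------------------
# Output transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutputTransforms:
    """Displacement normalization and range constraints on the outputs.

    Displacements: ``u_i* = N_i * std_i + mean_i``, optionally wrapped in the
    hard boundary constraint ``u* = g + l(x, y) * (N std + mean)`` with the
    window ``l = 16 x (1-x) y (1-y)`` (vanishing exactly on the boundary of
    the unit square, max 1 at the center) and particular solution
    ``g = (d(2x-1), d(2y-1))``.  Modulus: ``E* = 4 sigmoid(NE) + 1``, an open
    (1, 5) band with midpoint ``E*(0) = 3``.
    """

    u_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    u_std: np.ndarray = field(default_factory=lambda: np.ones(2))
    d: float = 0.2
    hard_bc: bool = False

    def __post_init__(self):
        object.__setattr__(self, "u_mean", np.asarray(self.u_mean, dtype=float))
        object.__setattr__(self, "u_std", np.asarray(self.u_std, dtype=float))
        if np.any(self.u_std <= 0):
            raise ValueError("displacement normalization std must be positive")

    @classmethod
    def from_reference(cls, u_ref: np.ndarray, d: float, hard_bc: bool) -> "OutputTransforms":
        """Normalization statistics taken from reference FEA displacements."""
        u_ref = np.asarray(u_ref, dtype=float)
        std = u_ref.std(axis=0)
        std[std <= 0] = 1.0
        return cls(u_mean=u_ref.mean(axis=0), u_std=std, d=d, hard_bc=hard_bc)

    @classmethod
    def default(cls, d: float, hard_bc: bool) -> "OutputTransforms":
        """Fallback statistics when no reference displacements exist: mean 0, std |d|."""
        std = abs(d) if d != 0 else 1.0
        return cls(u_mean=np.zeros(2), u_std=np.full(2, std), d=d, hard_bc=hard_bc)

    # -- window and particular solution (NumPy, constants per collocation set)
    def window(self, points: np.ndarray, order: int = 1) -> Bundle:
        x, y = points[:, 0], points[:, 1]
        wx, wy = x * (1.0 - x), y * (1.0 - y)
        b = Bundle(
            16.0 * wx * wy,
            16.0 * (1.0 - 2.0 * x) * wy,
            16.0 * wx * (1.0 - 2.0 * y),
        )
        if order >= 2:
            b.dxx = -32.0 * wy
            b.dxy = 16.0 * (1.0 - 2.0 * x) * (1.0 - 2.0 * y)
            b.dyy = -32.0 * wx
        return b

    def particular(self, points: np.ndarray) -> np.ndarray:
        return self.d * (2.0 * points - 1.0)

    def displacement(self, raw: Bundle, component: int, points: np.ndarray, order: int = 1) -> Bundle:
        """Transform one raw displacement bundle into the physical one."""
        m = self.u_mean[component]
        s = self.u_std[component]
        base = Bundle(
            raw.val * s + m,
            raw.dx * s,
            raw.dy * s,
            None if raw.dxx is None else raw.dxx * s,
            None if raw.dxy is None else raw.dxy * s,
            None if raw.dyy is None else raw.dyy * s,
        )
        if not self.hard_bc:
            return base
        ell = self.window(points, order)
        g = self.particular(points)[:, component]
        g_grad = 2.0 * self.d  # dg_x/dx = dg_y/dy = 2d, off-diagonal zero
        out = Bundle(
            g + ell.val * base.val,
            (g_grad if component == 0 else 0.0) + ell.dx * base.val + ell.val * base.dx,
            (g_grad if component == 1 else 0.0) + ell.dy * base.val + ell.val * base.dy,
        )
        if order >= 2:
            out.dxx = ell.dxx * base.val + 2.0 * (ell.dx * base.dx) + ell.val * base.dxx
            out.dxy = (
                ell.dxy * base.val
                + ell.dx * base.dy
                + ell.dy * base.dx
                + ell.val * base.dxy
            )
            out.dyy = ell.dyy * base.val + 2.0 * (ell.dy * base.dy) + ell.val * base.dyy
        return out

    def modulus(self, raw: Bundle, with_grad: bool = False) -> Bundle:
        """``E* = 4 sigmoid(NE) + 1`` (and its spatial gradient if requested)."""
        sig = sigmoid(raw.val)
        out = Bundle(4.0 * sig + 1.0)
        if with_grad:
            dsig = sig * (1.0 - sig)
            out._dx = 4.0 * (dsig * raw.dx)
            out._dy = 4.0 * (dsig * raw.dy)
        return out


def apply_output_transforms(
    raw_u: np.ndarray,
    raw_E: np.ndarray,
    points: np.ndarray,
    transforms: OutputTransforms,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain-NumPy convenience: transform raw outputs to ``(u*, E*)``.

    ``raw_u`` is (N, 2), ``raw_E`` is (N,).  Returns the physical
    displacement (N, 2) and modulus (N,) fields.
    """
    points = np.asarray(points, dtype=float)
    u = np.asarray(raw_u, dtype=float) * transforms.u_std + transforms.u_mean
    if transforms.hard_bc:
        x, y = points[:, 0], points[:, 1]
        ell = 16.0 * x * (1.0 - x) * y * (1.0 - y)
        u = transforms.particular(points) + ell[:, None] * u
    E = 4.0 * sigmoid(np.asarray(raw_E, dtype=float)) + 1.0
    return u, E
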