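"""Physics-informed inverse identification of heterogeneous moduli.

Networks map spatial coordinates to displacement, modulus and (topologies
I/II) first Piola-Kirchhoff stress outputs.  Training minimizes

``L = w_pde * L_PDE + w_const * L_const + w_data * L_data``

where ``L_data`` is the mean squared mismatch between the Green-Lagrange
strains derived from the network displacement (``F = I + grad u*``,
``eps = (F^T F - I)/2``) and the reference strains — displacements
themselves never enter the data loss; ``L_const`` (topologies I/II only)
ties the network stress outputs to the constitutive stress computed from
``u*`` and ``E*``; and ``L_PDE`` is the mean squared static equilibrium
residual ``Div P = 0``, taken on the network stress for I/II (first-order
derivatives only) and on the constitutive stress ``P(u*, E*)`` for III-V.

Collocation points are the finite-element nodes carrying the strain data.
Optimization is full-batch Adam; everything is deterministic under a fixed
seed.

With strain-only data and no traction information, a global rescaling of the
modulus leaves the equilibrium residual invariant; identifiability comes
from the (1, 5) output band together with synthetic truths whose minimum
touches the lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Tensor
from .constitutive import MaterialModel, stress_components
from .dual import Dual
from .forward import StrainField
from .metrics import l2_relative_error
from .networks import (
    ArchitectureSpec,
    Bundle,
    FCNN,
    OutputTransforms,
    input_features,
)

__all__ = [
    "LossWeights",
    "PINNModel",
    "pde_residual",
    "assemble_loss",
    "train",
    "PINNElasticityInverter",
]


@dataclass(frozen=True)
class LossWeights:
    """Composite-loss weights; the constitutive weight is ignored for FCNN III-V."""

    w_pde: float = 1.0
    w_const: float = 100.0
    w_data: float = 100.0

    def __post_init__(self):
        if min(self.w_pde, self.w_const, self.w_data) < 0:
            raise ValueError("loss weights must be non-negative")


class PINNModel:
    """An architecture instance plus its output transforms."""

    def __init__(
        self,
        spec: ArchitectureSpec,
        material: MaterialModel,
        transforms: OutputTransforms,
        dtype=np.float32,
    ):
        self.spec = spec
        self.material = material
        self.transforms = transforms
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(spec.seed)
        self.fcnn = FCNN(spec, rng, dtype=self.dtype)

    @property
    def parameters(self):
        return self.fcnn.parameters

    @property
    def pde_order(self) -> int:
        # I/II differentiate the network stress (first order); III-V
        # differentiate the constitutive stress of u*, needing second
        # derivatives of the displacement.
        return 1 if self.spec.has_stress_outputs else 2

    def _graph(self, points: np.ndarray, order: int | None = None):
        """Build the full computation graph at ``points``.

        Returns transformed displacement bundles, the modulus bundle, the
        deformation-gradient component tensors and (I/II) the raw stress
        bundles.
        """
        order = self.pde_order if order is None else order
        feats = input_features(points, self.spec.fourier, order, self.dtype)
        raw = self.fcnn.evaluate(feats, order)
        pts = points.astype(self.dtype)
        ux = self.transforms.displacement(raw["ux"], 0, pts, order)
        uy = self.transforms.displacement(raw["uy"], 1, pts, order)
        E = self.transforms.modulus(raw["E"], with_grad=not self.spec.has_stress_outputs)
        F = (1.0 + ux.dx, ux.dy, uy.dx, 1.0 + uy.dy)
        return ux, uy, E, F, raw.get("P")

    # -- numpy-facing evaluation ----------------------------------------------
    def predict_modulus(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        feats = input_features(points, self.spec.fourier, 1, self.dtype)
        raw = self.fcnn.evaluate(feats, 1)
        return np.asarray(self.transforms.modulus(raw["E"]).val.value, dtype=float)

    def predict_displacement(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        ux, uy, _, _, _ = self._graph(points, order=1)
        return np.column_stack([ux.val.value, uy.val.value]).astype(float)

    def predict_strains(self, points: np.ndarray) -> StrainField:
        points = np.asarray(points, dtype=float)
        _, _, _, F, _ = self._graph(points, order=1)
        F11, F12, F21, F22 = (f.value for f in F)
        return StrainField(
            points=points,
            exx=0.5 * (F11**2 + F21**2 - 1.0),
            eyy=0.5 * (F12**2 + F22**2 - 1.0),
            exy=0.5 * (F11 * F12 + F21 * F22),
        )


def _mse(t: Tensor) -> Tensor:
    return (t * t).mean()


def _loss_graph(model: PINNModel, points: np.ndarray, ref: np.ndarray, weights: LossWeights):
    """Tensors (total, L_pde, L_const, L_data); ``ref`` is (N, 3) strain data."""
    ux, uy, E, F, NP = model._graph(points)
    F11, F12, F21, F22 = F
    ref = ref.astype(model.dtype)

    exx = 0.5 * (F11 * F11 + F21 * F21 - 1.0)
    eyy = 0.5 * (F12 * F12 + F22 * F22 - 1.0)
    exy = 0.5 * (F11 * F12 + F21 * F22)
    L_data = (
        _mse(exx - ref[:, 0]) + _mse(eyy - ref[:, 1]) + _mse(exy - ref[:, 2])
    ) / 3.0

    if model.spec.has_stress_outputs:
        P_con = stress_components(F11, F12, F21, F22, E.val, model.material)
        L_const = sum(_mse(NP[i].val - P_con[i]) for i in range(4)) / 4.0
        r1 = NP[0].dx + NP[1].dy
        r2 = NP[2].dx + NP[3].dy
    else:
        Fd = (
            Dual(F11, ux.dxx, ux.dxy),
            Dual(F12, ux.dxy, ux.dyy),
            Dual(F21, uy.dxx, uy.dxy),
            Dual(F22, uy.dxy, uy.dyy),
        )
        Ed = Dual(E.val, E.dx, E.dy)
        P = stress_components(*Fd, Ed, model.material)
        L_const = None
        r1 = P[0].dx + P[1].dy
        r2 = P[2].dx + P[3].dy
    L_pde = (_mse(r1) + _mse(r2)) / 2.0

    total = weights.w_pde * L_pde + weights.w_data * L_data
    if L_const is not None:
        total = total + weights.w_const * L_const
    return total, L_pde, L_const, L_data


def pde_residual(model: PINNModel, points: np.ndarray) -> np.ndarray:
    """Static equilibrium residual ``Div P`` at ``points``, shape (N, 2)."""
    points = np.asarray(points, dtype=float)
    ux, uy, E, F, NP = model._graph(points)
    if model.spec.has_stress_outputs:
        r1 = NP[0].dx + NP[1].dy
        r2 = NP[2].dx + NP[3].dy
    else:
        F11, F12, F21, F22 = F
        Fd = (
            Dual(F11, ux.dxx, ux.dxy),
            Dual(F12, ux.dxy, ux.dyy),
            Dual(F21, uy.dxx, uy.dxy),
            Dual(F22, uy.dxy, uy.dyy),
        )
        P = stress_components(*Fd, Dual(E.val, E.dx, E.dy), model.material)
        r1 = P[0].dx + P[1].dy
        r2 = P[2].dx + P[3].dy
    return np.column_stack([r1.value, r2.value]).astype(float)


def assemble_loss(
    model: PINNModel,
    data: StrainField,
    weights: LossWeights = LossWeights(),
) -> dict:
    """Evaluate the composite loss and its components (floats)."""
    ref = data.as_array()
    total, L_pde, L_const, L_data = _loss_graph(model, data.points, ref, weights)
    return {
        "total": float(total.value),
        "pde": float(L_pde.value),
        "constitutive": None if L_const is None else float(L_const.value),
        "data": float(L_data.value),
    }


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.grad = None


def train(
    spec: ArchitectureSpec | str,
    material: MaterialModel,
    data: StrainField,
    weights: LossWeights = LossWeights(),
    iters: int = 20000,
    lr: float = 1e-3,
    seed: int | None = None,
    transforms: OutputTransforms | None = None,
    bc_d: float = 0.2,
    truth_modulus: np.ndarray | None = None,
    log_every: int = 1000,
    dtype=np.float32,
) -> tuple[PINNModel, list[dict]]:
    """Train a PINN on reference strain data at its collocation points.

    Returns the trained model and a history of logged loss components (and
    the L2 relative modulus error when ``truth_modulus`` is supplied).
    Raises ``FloatingPointError`` if the loss becomes non-finite.
    """
    if isinstance(spec, str):
        spec = ArchitectureSpec.from_code(spec, seed=seed or 0)
    elif seed is not None and seed != spec.seed:
        spec = ArchitectureSpec(
            fcnn=spec.fcnn, fourier=spec.fourier, hard_bc=spec.hard_bc, seed=seed
        )
    if transforms is None:
        transforms = OutputTransforms.default(bc_d, spec.hard_bc)
    model = PINNModel(spec, material, transforms, dtype=dtype)
    points = np.asarray(data.points, dtype=float)
    ref = data.as_array()
    opt = _Adam(model.parameters, lr=lr)
    history: list[dict] = []

    for it in range(iters):
        total, L_pde, L_const, L_data = _loss_graph(model, points, ref, weights)
        if not np.isfinite(total.value):
            raise FloatingPointError(f"training diverged at iteration {it}")
        total.backward()
        opt.step()
        if it % log_every == 0 or it == iters - 1:
            rec = {
                "iteration": it,
                "pde": float(L_pde.value),
                "constitutive": None if L_const is None else float(L_const.value),
                "data": float(L_data.value),
                "total": float(total.value),
            }
            if truth_modulus is not None:
                rec["l2_error"] = float(
                    l2_relative_error(model.predict_modulus(points), truth_modulus)
                )
            history.append(rec)
    return model, history


class PINNElasticityInverter(BaseEstimator):
    """Scikit-learn style estimator recovering a modulus field from strains.

    ``fit(X, y)`` takes collocation coordinates ``X`` (n, 2) and reference
    Green-Lagrange strains ``y`` (n, 3, columns exx/eyy/exy) and trains the
    chosen architecture; ``predict(X)`` evaluates the recovered modulus at
    arbitrary coordinates.

    Parameters
    ----------
    arch : str
        Architecture code, FCNN numeral I-V plus variant letter A-D
        (A standard + hard BC, B standard, C Fourier + hard BC, D Fourier).
    material : MaterialModel
        Constitutive family with its known parameters.
    bc_d : float
        Equibiaxial boundary displacement per side (used by the hard
        constraint and the default displacement normalization).
    u_stats : (mean, std) arrays, optional
        Displacement normalization statistics, e.g. from reference FEA.

    Attributes
    ----------
    model_ : PINNModel
        The trained network with its transforms.
    modulus_ : ndarray (n,)
        Recovered modulus at the training collocation points.
    history_ : list of dict
        Logged loss components.
    """

    def __init__(
        self,
        arch: str = "IIB",
        material: MaterialModel = MaterialModel(),
        bc_d: float = 0.2,
        w_pde: float = 1.0,
        w_const: float = 100.0,
        w_data: float = 100.0,
        iters: int = 20000,
        lr: float = 1e-3,
        seed: int = 0,
        dtype: str = "float32",
        log_every: int = 1000,
        u_stats: tuple | None = None,
    ):
        self.arch = arch
        self.material = material
        self.bc_d = bc_d
        self.w_pde = w_pde
        self.w_const = w_const
        self.w_data = w_data
        self.iters = iters
        self.lr = lr
        self.seed = seed
        self.dtype = dtype
        self.log_every = log_every
        self.u_stats = u_stats

    def fit(self, X, y, truth_modulus: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or y.shape != (len(X), 3):
            raise ValueError("X must be (n, 2) coordinates and y (n, 3) strains")
        spec = ArchitectureSpec.from_code(self.arch, seed=self.seed)
        if self.u_stats is not None:
            mean, std = self.u_stats
            transforms = OutputTransforms(
                u_mean=mean, u_std=std, d=self.bc_d, hard_bc=spec.hard_bc
            )
        else:
            transforms = OutputTransforms.default(self.bc_d, spec.hard_bc)
        data = StrainField.from_array(X, y)
        self.model_, self.history_ = train(
            spec,
            self.material,
            data,
            weights=LossWeights(self.w_pde, self.w_const, self.w_data),
            iters=self.iters,
            lr=self.lr,
            transforms=transforms,
            bc_d=self.bc_d,
            truth_modulus=truth_modulus,
            log_every=self.log_every,
            dtype=np.dtype(self.dtype).type,
        )
        self.modulus_ = self.model_.predict_modulus(X)
        self.displacement_ = self.model_.predict_displacement(X)
        self.loss_ = self.history_[-1]["total"] if self.history_ else None
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return self.model_.predict_modulus(np.asarray(X, dtype=float))
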