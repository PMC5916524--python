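"""Drift, diffusion, and convective fields on concentration space.

For a network with stoichiometric matrix S and concentration-space
propensities ν(x) the drift is f = S·ν, the diffusion matrix is
D = S·diag(ν)·Sᵀ, and the convective field is

    α_i(x) = f_i(x) − (1/2N) Σ_k ∂D_ik/∂x_k.

Propensities keep their finite-size combinatorial factors, e.g. a binary
self-interaction contributes x(x − 1/N).  All fields are constructed
symbolically; derivatives are taken exactly by default, with a central
finite-difference fallback for black-box use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

from .reaction_network import (
    NetworkError,
    ReactionNetwork,
    reactant_matrix,
    stoichiometric_matrix,
)

__all__ = [
    "SymbolicFields",
    "FieldModel",
    "CurrentField",
    "drift",
    "diffusion_matrix",
    "convective_field",
    "probability_current",
    "finite_difference_jacobian",
]

#: central-difference step scale: cube root of machine epsilon
_FD_SCALE = float(np.finfo(float).eps) ** (1.0 / 3.0)


class SymbolicFields:
    """Exact symbolic drift/diffusion/convective field of a network.

    Species symbols stand for concentrations x_i = n_i/N; the symbol
    ``invN`` stands for 1/N so that the thermodynamic limit is the
    substitution invN → 0.  Parameter symbols remain free.
    """

    def __init__(self, net: ReactionNetwork):
        self.network = net
        self.x = tuple(sp.Symbol(s) for s in net.species)
        self.invN = sp.Symbol("invN", nonnegative=True)
        sigma = reactant_matrix(net)
        Smat = stoichiometric_matrix(net)
        self.S = sp.Matrix(Smat.entries.tolist())

        nu = []
        for j, rxn in enumerate(net.reactions):
            expr = rxn.rate
            for z, xz in enumerate(self.x):
                for l in range(sigma[z, j]):
                    expr = expr * (xz - l * self.invN)
            nu.append(sp.expand(expr))
        k = len(self.x)
        if nu:
            self.nu = sp.Matrix(nu)
            self.f = self.S * self.nu
            self.D = self.S * sp.diag(*nu) * self.S.T
        else:
            self.nu = sp.zeros(0, 1)
            self.f = sp.zeros(k, 1)
            self.D = sp.zeros(k, k)
        k = len(self.x)
        self.divD = sp.Matrix(
            [sum(sp.diff(self.D[i, j], self.x[j]) for j in range(k)) for i in range(k)]
        )
        self.alpha = self.f - (self.invN / 2) * self.divD
        self.jac_f = self.f.jacobian(self.x)
        self.jac_alpha = self.alpha.jacobian(self.x)


def _lambdify(args, expr, shape=None):
    fn = sp.lambdify(args, expr, modules="numpy")

    def wrapped(x):
        out = np.asarray(fn(*np.asarray(x, dtype=float)), dtype=float)
        return out if shape is None else out.reshape(shape)

    return wrapped


@dataclass
class FieldModel:
    """Numeric field bundle for one network at fixed parameters and N.

    ``derivative_policy`` selects how ∂D/∂x (inside α) and Jacobians are
    computed: ``"symbolic"`` (exact) or ``"fd"`` (central differences).
    """

    network: ReactionNetwork
    sym: SymbolicFields
    N: float
    params: Mapping[str, float]
    derivative_policy: str = "symbolic"

    @classmethod
    def from_network(
        cls,
        net: ReactionNetwork,
        params: Mapping[str, float] | None = None,
        N: float | None = None,
        derivative_policy: str = "symbolic",
    ) -> "FieldModel":
        if derivative_policy not in ("symbolic", "fd"):
            raise ValueError(f"unknown derivative_policy {derivative_policy!r}")
        table = {**net.parameters, **(params or {})}
        Nval = float(N if N is not None else net.system_size)
        if not Nval > 0:
            raise NetworkError("N must be positive")
        sym = SymbolicFields(net)
        model = cls(net, sym, Nval, table, derivative_policy)
        model._compile()
        return model

    # -- compilation -------------------------------------------------------

    def _subs(self) -> dict:
        table = {sp.Symbol(k): float(v) for k, v in self.params.items()}
        table[self.sym.invN] = 0.0 if np.isinf(self.N) else 1.0 / self.N
        return table

    def _compile(self) -> None:
        sym, subs = self.sym, self._subs()
        k = len(sym.x)
        for name in ("f", "D", "alpha", "nu", "jac_f", "jac_alpha"):
            expr = getattr(sym, name).subs(subs)
            free = expr.free_symbols - set(sym.x)
            if free:
                raise NetworkError(
                    f"unresolved parameters {sorted(map(str, free))} in field model"
                )
        self.k = k
        self._f = _lambdify(sym.x, list(sym.f.subs(subs)))
        self._D = _lambdify(sym.x, sym.D.subs(subs), shape=(k, k))
        self._alpha = _lambdify(sym.x, list(sym.alpha.subs(subs)))
        self._jac_f = _lambdify(sym.x, sym.jac_f.subs(subs), shape=(k, k))
        self._jac_alpha = _lambdify(sym.x, sym.jac_alpha.subs(subs), shape=(k, k))

    # -- evaluation --------------------------------------------------------

    def _check(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.k,):
            raise NetworkError(f"expected {self.k}-vector, got shape {x.shape}")
        return x

    def f(self, x: Sequence[float]) -> np.ndarray:
        """Deterministic drift S·ν(x)."""
        return self._f(self._check(x))

    def D(self, x: Sequence[float]) -> np.ndarray:
        """Diffusion matrix S·diag(ν)·Sᵀ (symmetric)."""
        return self._D(self._check(x))

    def alpha(self, x: Sequence[float]) -> np.ndarray:
        """Convective field f − (1/2N)·div D."""
        x = self._check(x)
        if self.derivative_policy == "symbolic":
            return self._alpha(x)
        divD = self._div_D_fd(x)
        if not np.all(np.isfinite(divD)):
            bad = int(np.flatnonzero(~np.isfinite(divD))[0])
            raise FloatingPointError(
                f"non-finite divergence of D in component {self.network.species[bad]}"
            )
        invN = 0.0 if np.isinf(self.N) else 1.0 / self.N
        return self._f(x) - 0.5 * invN * divD

    def jacobian_f(self, x: Sequence[float]) -> np.ndarray:
        x = self._check(x)
        if self.derivative_policy == "symbolic":
            return self._jac_f(x)
        return finite_difference_jacobian(self.f, x)

    def jacobian_alpha(self, x: Sequence[float]) -> np.ndarray:
        """Jacobian (J_s)_ik = ∂α_i/∂x_k of the convective field."""
        x = self._check(x)
        if self.derivative_policy == "symbolic":
            return self._jac_alpha(x)
        return finite_difference_jacobian(self.alpha, x)

    def _div_D_fd(self, x: np.ndarray) -> np.ndarray:
        div = np.zeros(self.k)
        for kk in range(self.k):
            h = _FD_SCALE * (1.0 + abs(x[kk]))
            xp, xm = x.copy(), x.copy()
            xp[kk] += h
            xm[kk] -= h
            div += (self._D(xp)[:, kk] - self._D(xm)[:, kk]) / (2 * h)
        return div


def finite_difference_jacobian(field: Callable, x: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of a vector field."""
    x = np.asarray(x, dtype=float)
    k = x.size
    J = np.empty((k, k))
    for col in range(k):
        h = _FD_SCALE * (1.0 + abs(x[col]))
        xp, xm = x.copy(), x.copy()
        xp[col] += h
        xm[col] -= h
        J[:, col] = (np.asarray(field(xp)) - np.asarray(field(xm))) / (2 * h)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite entries in finite-difference Jacobian")
    return J


# Convenience wrappers matching the operation names.

def drift(model: FieldModel, x) -> np.ndarray:
    return model.f(x)


def diffusion_matrix(model: FieldModel, x) -> np.ndarray:
    return model.D(x)


def convective_field(model: FieldModel, x, N: float | None = None) -> np.ndarray:
    """α at ``x``; pass ``N`` to evaluate at a system size other than the
    model's (rebuilds nothing, uses the exact 1/N dependence)."""
    if N is None or N == model.N:
        return model.alpha(x)
    rebuilt = FieldModel.from_network(
        model.network, params=model.params, N=N, derivative_policy=model.derivative_policy
    )
    return rebuilt.alpha(x)


@dataclass
class CurrentField:
    """Probability current j(x) = α·p − (1/2N)·D·∇p for one field model."""

    model: FieldModel

    def j(self, x, p: float, grad_p: Sequence[float]) -> np.ndarray:
        if p < 0:
            raise ValueError("density value must be non-negative")
        invN = 0.0 if np.isinf(self.model.N) else 1.0 / self.model.N
        grad_p = np.asarray(grad_p, dtype=float)
        return self.model.alpha(x) * p - 0.5 * invN * (self.model.D(x) @ grad_p)


def probability_current(model: FieldModel, x, p: float, grad_p) -> np.ndarray:
    return CurrentField(model).j(x, p, grad_p)
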