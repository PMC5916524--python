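"""Stochastic bifurcation detection under parameter or system-size sweeps.

Three event types are located by bisection:

* ``eigenvalue-crossing`` — the leading non-structural eigenvalue of the
  convective-field Jacobian at a tracked fixed point crosses zero;
* ``nullcline-gap`` — the perpendicular convective-flow component at the
  boundary-maximum location on an axis reverses sign (negative means the
  flow presses into the boundary and a boundary maximum exists);
* ``nullcline-detachment`` — the interior fixed point disappears as the
  nullcline families cease to intersect.

The nullcline-gap event function is an operational formalization of a
pictorially defined transition; it is validated against printed brackets
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .fields import FieldModel
from .phase_portrait import (
    BoundaryMaximum,
    FixedPointRecord,
    boundary_maxima,
    find_fixed_points,
    jacobian,
)
from .reaction_network import conservation_laws, stoichiometric_matrix

__all__ = [
    "SweepResult",
    "eigenvalue_crossing",
    "nullcline_gap_critical_size",
    "nullcline_detachment",
    "sweep",
]

log = logging.getLogger(__name__)

DEFAULT_BISECTION_DEPTH = 40


def _field_and_jac(model) -> tuple[Callable, Callable | None]:
    if isinstance(model, FieldModel):
        return model.alpha, model.jacobian_alpha
    return model, None


def _n_structural_zeros(model) -> int:
    if isinstance(model, FieldModel):
        return len(conservation_laws(stoichiometric_matrix(model.network)))
    return 0


def _refine_root(fieldfn, jac, x0, tol=1e-12, max_iter=60) -> np.ndarray | None:
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        F = np.asarray(fieldfn(x), dtype=float)
        if np.linalg.norm(F) < tol:
            return x
        J = jacobian(fieldfn, x, jac)
        step, *_ = np.linalg.lstsq(J, -F, rcond=None)
        if not np.all(np.isfinite(step)):
            return None
        x = x + step
    return x if np.linalg.norm(fieldfn(x)) < 1e-8 else None


def leading_eigenvalue(model, x: Sequence[float]) -> float:
    """Max real part of J_s eigenvalues, excluding structurally zero modes.

    Conservation laws force one zero eigenvalue per law; the corresponding
    modes (smallest |λ|) are dropped before taking the maximum.
    """
    fieldfn, jac = _field_and_jac(model)
    J = jacobian(fieldfn, np.asarray(x, dtype=float), jac)
    eig = np.linalg.eigvals(J)
    n_zero = _n_structural_zeros(model)
    if n_zero:
        order = np.argsort(np.abs(eig))
        eig = eig[order[n_zero:]]
    if eig.size == 0:
        raise ValueError("all eigenvalues are structural zeros")
    return float(np.max(eig.real))


def eigenvalue_crossing(
    build: Callable[[float], object],
    interval: tuple[float, float],
    x0: Sequence[float],
    rtol: float = 1e-6,
) -> float | None:
    """Parameter value where the tracked fixed point changes stability.

    ``build(p)`` returns a :class:`FieldModel` (or bare field callable);
    the fixed point is re-refined from ``x0`` at every evaluation.  Returns
    ``None`` when the leading eigenvalue does not change sign on the
    interval.
    """
    state = {"x": np.asarray(x0, dtype=float)}

    def event(p: float) -> float:
        model = build(p)
        fieldfn, jac = _field_and_jac(model)
        x = _refine_root(fieldfn, jac, state["x"])
        if x is None:
            raise RuntimeError(f"lost track of the fixed point at parameter {p}")
        state["x"] = x
        return leading_eigenvalue(model, x)

    a, b = interval
    fa, fb = event(a), event(b)
    if fa * fb > 0:
        return None
    return float(brentq(event, a, b, rtol=rtol, xtol=1e-15))


def largest_axis_root(
    model, x_range: tuple[float, float], axis: int = 0, n_scan: int = 512
) -> BoundaryMaximum | None:
    """Largest root of the parallel α component on a coordinate axis."""
    fieldfn, _ = _field_and_jac(model)
    domain = [(0.0, 0.0), (0.0, 0.0)]
    domain[axis] = x_range
    domain[1 - axis] = (0.0, 1.0)  # unused by the axis scan
    cands = [
        bm for bm in boundary_maxima(fieldfn, domain, n_scan=n_scan) if bm.axis == axis
    ]
    if not cands:
        return None
    return max(cands, key=lambda bm: bm.location[axis])


def nullcline_gap_critical_size(
    build: Callable[[float], object],
    N_interval: tuple[float, float],
    x_range: tuple[float, float] = (1.0, 15.0),
    axis: int = 0,
    tol: float = 1e-9,
    max_depth: int = DEFAULT_BISECTION_DEPTH,
) -> tuple[float, tuple[float, float]] | None:
    """Critical system size of the nullcline-gap bifurcation, with bracket.

    The event function g(N) is the perpendicular convective-field component
    at the boundary-maximum location on the given axis: g < 0 means inflow
    (boundary maximum exists), g > 0 means the interior holds the
    probability.  Returns ``(N*, (lo, hi))`` or ``None`` when g has the
    same sign at both interval ends.
    """

    def g(N: float) -> float:
        model = build(N)
        bm = largest_axis_root(model, x_range, axis=axis)
        if bm is None:
            raise RuntimeError(f"no boundary nullcline root at N={N}")
        log.debug("nullcline-gap sweep: N=%g x*=%g g=%g", N, bm.location[axis],
                  bm.perpendicular_component)
        return bm.perpendicular_component

    a, b = float(N_interval[0]), float(N_interval[1])
    try:
        ga, gb = g(a), g(b)
    except RuntimeError:
        return None
    if ga * gb > 0:
        return None
    for _ in range(max_depth):
        mid = 0.5 * (a + b)
        gm = g(mid)
        if abs(gm) < tol:
            return mid, (a, b)
        if ga * gm <= 0:
            b, gb = mid, gm
        else:
            a, ga = mid, gm
    return 0.5 * (a + b), (a, b)


def nullcline_detachment(
    build: Callable[[float], object],
    N_interval: tuple[float, float],
    domain: Sequence[tuple[float, float]],
    xtol: float = 0.5,
    n_starts: int = 64,
    seed: int = 0,
    boundary_margin: float = 1e-3,
) -> float | None:
    """Critical N at which the interior fixed point count drops from ≥1 to 0.

    Boolean bisection on the existence of a root of α strictly inside the
    domain (a ``boundary_margin`` fraction away from every face).
    """
    lo = np.array([d[0] for d in domain], dtype=float)
    hi = np.array([d[1] for d in domain], dtype=float)
    margin = boundary_margin * (hi - lo)

    def has_interior(N: float) -> bool:
        model = build(N)
        fieldfn, jac = _field_and_jac(model)
        fps = find_fixed_points(fieldfn, domain, n_starts=n_starts, seed=seed, jac=jac)
        return any(
            np.all(fp.location > lo + margin) and np.all(fp.location < hi - margin)
            for fp in fps
        )

    a, b = float(N_interval[0]), float(N_interval[1])
    ha, hb = has_interior(a), has_interior(b)
    if ha == hb:
        return None
    while b - a > xtol:
        mid = 0.5 * (a + b)
        if has_interior(mid) == ha:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


@dataclass
class SweepEvent:
    type: str  # eigenvalue-crossing | nullcline-gap | nullcline-detachment
    critical_value: float
    bracket: tuple[float, float]


@dataclass
class SweepResult:
    parameter: str
    values: list[float]
    fixed_points: list[list[FixedPointRecord]]
    boundary: list[list[BoundaryMaximum]]
    events: list[SweepEvent] = field(default_factory=list)


def sweep(
    build: Callable[[float], object],
    parameter: str,
    values: Sequence[float],
    domain: Sequence[tuple[float, float]],
    n_starts: int = 64,
    seed: int = 0,
) -> SweepResult:
    """Evaluate fixed points and boundary maxima at each parameter value and
    bracket sign changes of the boundary-inflow indicator."""
    values = [float(v) for v in values]
    fps, bnd = [], []
    for v in values:
        model = build(v)
        fieldfn, jac = _field_and_jac(model)
        fps.append(find_fixed_points(fieldfn, domain, n_starts=n_starts, seed=seed, jac=jac))
        bnd.append(boundary_maxima(fieldfn, domain))
        log.info("sweep %s=%g: %d fixed points, %d boundary candidates",
                 parameter, v, len(fps[-1]), len(bnd[-1]))
    result = SweepResult(parameter, values, fps, bnd)
    for (v0, b0), (v1, b1) in zip(zip(values, bnd), zip(values[1:], bnd[1:])):
        f0 = any(bm.inflow for bm in b0)
        f1 = any(bm.inflow for bm in b1)
        if f0 != f1:
            result.events.append(
                SweepEvent("nullcline-gap", 0.5 * (v0 + v1), (min(v0, v1), max(v0, v1)))
            )
    return result
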