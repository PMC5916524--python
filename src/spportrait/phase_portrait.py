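"""Stochastic phase portraits: fixed points of the convective field with
classification, nullclines, trajectories, limit cycles, and boundary maxima.

All operations take the field as a plain callable ``x -> vector`` so they
work both for :class:`~spportrait.fields.FieldModel` fields (pass
``model.alpha`` with ``jac=model.jacobian_alpha``) and for toy fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from contourpy import contour_generator
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import qmc

from .fields import finite_difference_jacobian

__all__ = [
    "FixedPointRecord",
    "PhasePortrait",
    "Cycle",
    "Trajectory",
    "BoundaryMaximum",
    "find_fixed_points",
    "jacobian",
    "classify",
    "nullclines",
    "integrate_trajectory",
    "detect_limit_cycle",
    "boundary_maxima",
    "compute_portrait",
]

log = logging.getLogger(__name__)

STABLE_CLASSES = frozenset({"stable-node", "stable-spiral"})
UNSTABLE_CLASSES = frozenset({"unstable-node", "unstable-spiral"})


@dataclass
class FixedPointRecord:
    location: np.ndarray
    residual: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str
    favorable_candidate: bool

    @property
    def is_stable(self) -> bool:
        return self.classification in STABLE_CLASSES


def jacobian(fieldfn: Callable, x, jac: Callable | None = None) -> np.ndarray:
    """Jacobian of a vector field by the active derivative policy."""
    if jac is not None:
        J = np.asarray(jac(x), dtype=float)
        if not np.all(np.isfinite(J)):
            raise FloatingPointError("non-finite Jacobian entries")
        return J
    return finite_difference_jacobian(fieldfn, np.asarray(x, dtype=float))


def classify(eigenvalues: np.ndarray, zero_tol: float | None = None) -> str:
    """Map the eigenvalue sign pattern to a fixed-point class.

    Any real part below ``zero_tol`` in magnitude yields the
    ``marginal/manifold`` class (conservation laws produce structurally zero
    modes).  Default tolerance: 1e-8 · max|λ| with an absolute floor.
    """
    eig = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    scale = float(np.max(np.abs(eig))) if eig.size else 0.0
    if zero_tol is None:
        zero_tol = max(1e-8 * scale, 1e-14)
    re = eig.real
    if np.any(np.abs(re) < zero_tol):
        return "marginal/manifold"
    spiral = bool(np.any(np.abs(eig.imag) > zero_tol))
    if np.all(re < 0):
        return "stable-spiral" if spiral else "stable-node"
    if np.all(re > 0):
        return "unstable-spiral" if spiral else "unstable-node"
    return "saddle"


def _record(fieldfn, x, jac, zero_tol=None) -> FixedPointRecord:
    J = jacobian(fieldfn, x, jac)
    eig = np.linalg.eigvals(J)
    cls = classify(eig, zero_tol)
    scale = float(np.max(np.abs(eig))) if eig.size else 0.0
    tol = zero_tol if zero_tol is not None else max(1e-8 * scale, 1e-14)
    return FixedPointRecord(
        location=np.asarray(x, dtype=float),
        residual=float(np.linalg.norm(fieldfn(x))),
        jacobian=J,
        eigenvalues=eig,
        classification=cls,
        favorable_candidate=bool(np.all(eig.real < -tol)),
    )


def find_fixed_points(
    fieldfn: Callable,
    domain: Sequence[tuple[float, float]],
    n_starts: int = 64,
    seed: int = 0,
    jac: Callable | None = None,
    root_tol: float = 1e-9,
    max_iter: int = 100,
) -> list[FixedPointRecord]:
    """Deduplicated roots of the field inside the closed box ``domain``.

    Damped Newton (least-squares step, so rank-deficient Jacobians on
    fixed-point manifolds are handled) from a scrambled-Sobol multistart;
    deterministic for a given seed.  Roots closer than 1e-6 times the domain
    diagonal are merged.
    """
    domain = [(float(lo), float(hi)) for lo, hi in domain]
    k = len(domain)
    lo = np.array([d[0] for d in domain])
    hi = np.array([d[1] for d in domain])
    diag = float(np.linalg.norm(hi - lo))
    merge_tol = 1e-6 * diag

    sampler = qmc.Sobol(d=k, scramble=True, seed=seed)
    n_pow2 = 1 << max(0, int(np.ceil(np.log2(max(n_starts, 1)))))
    starts = lo + sampler.random(n_pow2)[:n_starts] * (hi - lo)

    roots: list[np.ndarray] = []
    for x0 in starts:
        x = x0.copy()
        ok = False
        for _ in range(max_iter):
            F = np.asarray(fieldfn(x), dtype=float)
            nF = np.linalg.norm(F)
            if nF < root_tol:
                ok = True
                break
            try:
                J = jacobian(fieldfn, x, jac)
            except FloatingPointError:
                break
            step, *_ = np.linalg.lstsq(J, -F, rcond=None)
            if not np.all(np.isfinite(step)):
                break
            lam = 1.0
            while lam > 1e-12:
                xn = x + lam * step
                if np.linalg.norm(fieldfn(xn)) <= (1 - 1e-4 * lam) * nF:
                    break
                lam *= 0.5
            else:
                break
            x = x + lam * step
        if not ok:
            continue
        if np.any(x < lo - 1e-9 * (1 + np.abs(lo))) or np.any(x > hi + 1e-9 * (1 + np.abs(hi))):
            continue
        if all(np.linalg.norm(x - r) > merge_tol for r in roots):
            roots.append(x)

    if not roots:
        log.warning("find_fixed_points: no convergence from any of %d starts", n_starts)
    return [_record(fieldfn, x, jac) for x in roots]


def nullclines(
    fieldfn: Callable,
    domain: Sequence[tuple[float, float]],
    resolution: int = 256,
) -> dict[int, list[np.ndarray]]:
    """Zero-level contours of each field component on a 2D sampled grid.

    Returns ``{component index: [polyline (n,2) arrays]}``; a component
    that never changes sign yields an empty list.
    """
    if len(domain) != 2:
        raise ValueError("nullclines requires a 2D domain")
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    xs = np.linspace(domain[0][0], domain[0][1], resolution)
    ys = np.linspace(domain[1][0], domain[1][1], resolution)
    Z = np.empty((2, resolution, resolution))
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            Z[:, iy, ix] = fieldfn((x, y))
    X, Y = np.meshgrid(xs, ys)
    out: dict[int, list[np.ndarray]] = {}
    for comp in range(2):
        gen = contour_generator(x=X, y=Y, z=Z[comp])
        out[comp] = [np.asarray(line) for line in gen.lines(0.0) if len(line) > 1]
    return out


@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # (n, k)
    truncated: bool = False


def integrate_trajectory(
    fieldfn: Callable,
    x0: Sequence[float],
    t_max: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: np.ndarray | None = None,
    max_step: float = np.inf,
    clip: bool = True,
) -> Trajectory:
    """Integrate dx/dt = field(x), clipped to the non-negative orthant.

    On a boundary face with outward-pointing field, the component normal to
    the face is zeroed, so the path slides along the boundary.  Pass
    ``clip=False`` for fields defined on all of state space.
    """
    x0 = np.asarray(x0, dtype=float)

    if clip:
        def rhs(_t, x):
            xc = np.maximum(x, 0.0)
            v = np.asarray(fieldfn(xc), dtype=float)
            v[(xc <= 0.0) & (v < 0.0)] = 0.0
            return v
    else:
        def rhs(_t, x):
            return np.asarray(fieldfn(x), dtype=float)

    sol = solve_ivp(
        rhs, (0.0, float(t_max)), x0, method="RK45",
        rtol=rtol, atol=atol, t_eval=t_eval, max_step=max_step, dense_output=False,
    )
    y = sol.y.T
    if clip:
        y = np.maximum(y, 0.0)
    return Trajectory(t=sol.t, y=y, truncated=not sol.success)


@dataclass
class Cycle:
    points: np.ndarray  # (n, k), closed orbit sample (one period)
    times: np.ndarray
    speeds: np.ndarray  # ‖field‖ along the orbit
    period: float

    @property
    def speed_ratio(self) -> float:
        smin = float(np.min(self.speeds))
        return float(np.max(self.speeds)) / smin if smin > 0 else np.inf


def detect_limit_cycle(
    path: Trajectory,
    fieldfn: Callable,
    cycle_tol: float | None = None,
    domain_diag: float | None = None,
) -> Cycle | None:
    """Nearest-return recurrence test on the last half of a trajectory.

    Returns one period and the speed profile ‖field‖ along it when the
    endpoint recurs within ``cycle_tol`` (default 1e-3 times the domain
    diagonal, estimated from the path extent when not given); otherwise
    ``None``.  Speed minima mark slow-transient-state candidates.
    """
    y = path.y
    t = path.t
    half = len(t) // 2
    pts, ts = y[half:], t[half:]
    if len(pts) < 8:
        return None
    extent = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    if domain_diag is None:
        domain_diag = extent if extent > 0 else 1.0
    if cycle_tol is None:
        cycle_tol = 1e-3 * domain_diag
    if extent < 10 * cycle_tol:  # converged to a point
        return None

    ref = pts[-1]
    d = np.linalg.norm(pts - ref, axis=1)
    far = max(10 * cycle_tol, 0.2 * extent)

    def seg_dist(i: int) -> tuple[float, float]:
        """Distance from ref to segment (i, i+1) and the projection fraction."""
        seg = pts[i + 1] - pts[i]
        denom = float(seg @ seg)
        frac = 0.0 if denom == 0 else float(np.clip((ref - pts[i]) @ seg / denom, 0.0, 1.0))
        return float(np.linalg.norm(pts[i] + frac * seg - ref)), frac

    # walk backwards: first leave the neighborhood of the endpoint, then
    # look for the previous pass of the polyline within cycle_tol of it
    i = len(pts) - 2
    while i >= 0 and d[i] < far:
        i -= 1
    frac = 0.0
    while i >= 0:
        dist, frac = seg_dist(i)
        if dist < cycle_tol:
            break
        i -= 1
    if i < 0:
        return None

    seg = pts[i + 1] - pts[i]
    start = pts[i] + frac * seg
    t_start = ts[i] + frac * (ts[i + 1] - ts[i])

    orbit = np.vstack([start, pts[i + 1:]])
    times = np.concatenate([[t_start], ts[i + 1:]])
    speeds = np.array([np.linalg.norm(fieldfn(p)) for p in orbit])
    return Cycle(points=orbit, times=times, speeds=speeds, period=float(ts[-1] - t_start))


@dataclass
class BoundaryMaximum:
    axis: int  # which axis the point lies on (0 → x-axis, i.e. y = 0)
    location: np.ndarray
    inflow: bool  # perpendicular field component points into the boundary
    perpendicular_component: float


def boundary_maxima(
    fieldfn: Callable,
    domain: Sequence[tuple[float, float]],
    n_scan: int = 512,
) -> list[BoundaryMaximum]:
    """Boundary-maximum candidates of a 2D field on the coordinate axes.

    For each axis, finds the roots of the parallel field component
    restricted to that axis (where the corresponding nullcline intersects
    its own axis) and flags ``inflow=True`` when the perpendicular
    component points into the boundary (negative), the condition under
    which a boundary maximum forms.
    """
    if len(domain) != 2:
        raise ValueError("boundary_maxima requires a 2D domain")
    out: list[BoundaryMaximum] = []
    for axis in (0, 1):
        perp = 1 - axis
        lo, hi = domain[axis]
        lo = max(lo, 0.0)

        def par(s, axis=axis):
            p = [0.0, 0.0]
            p[axis] = s
            return float(fieldfn(p)[axis])

        ss = np.linspace(lo, hi, n_scan)
        vals = np.array([par(s) for s in ss])
        for a, b, va, vb in zip(ss[:-1], ss[1:], vals[:-1], vals[1:]):
            if va == 0.0:
                root = a
            elif va * vb < 0:
                root = brentq(par, a, b, xtol=1e-12, rtol=1e-12)
            else:
                continue
            p = [0.0, 0.0]
            p[axis] = root
            perp_val = float(fieldfn(p)[perp])
            out.append(
                BoundaryMaximum(
                    axis=axis,
                    location=np.asarray(p, dtype=float),
                    inflow=perp_val < 0.0,
                    perpendicular_component=perp_val,
                )
            )
    return out


@dataclass
class PhasePortrait:
    """Assembled portrait of dx/dt = α(x) on a 2D box."""

    grid: np.ndarray  # (n, 2) sample points
    vectors: np.ndarray  # (n, 2) field values
    nullclines: dict[int, list[np.ndarray]]
    fixed_points: list[FixedPointRecord]
    trajectories: list[Trajectory] = field(default_factory=list)
    boundary_maxima: list[BoundaryMaximum] = field(default_factory=list)


def compute_portrait(
    fieldfn: Callable,
    domain: Sequence[tuple[float, float]],
    jac: Callable | None = None,
    resolution: int = 24,
    nullcline_resolution: int = 256,
    n_starts: int = 64,
    seed: int = 0,
    trajectories_from: Sequence[Sequence[float]] = (),
    t_max: float = 100.0,
) -> PhasePortrait:
    """One-call portrait assembly (grid, nullclines, roots, trajectories)."""
    xs = np.linspace(domain[0][0], domain[0][1], resolution)
    ys = np.linspace(domain[1][0], domain[1][1], resolution)
    grid = np.array([(x, y) for y in ys for x in xs])
    vectors = np.array([fieldfn(p) for p in grid])
    return PhasePortrait(
        grid=grid,
        vectors=vectors,
        nullclines=nullclines(fieldfn, domain, nullcline_resolution),
        fixed_points=find_fixed_points(fieldfn, domain, n_starts=n_starts, seed=seed, jac=jac),
        trajectories=[integrate_trajectory(fieldfn, x0, t_max) for x0 in trajectories_from],
        boundary_maxima=boundary_maxima(fieldfn, domain),
    )
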