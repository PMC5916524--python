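"""Exact stochastic simulation (direct-method SSA) and stationary histograms.

The sampler draws exponential waiting times with total rate N·Σ_j ν_j(n)
and picks the next reaction proportional to its propensity, updating the
state by the corresponding stoichiometric column.  Histograms are
time-weighted (weight = holding time) over concentration space x = n/N
with bin edges aligned to multiples of 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.ndimage import gaussian_filter, maximum_filter

from .reaction_network import (
    NetworkError,
    ReactionNetwork,
    reactant_matrix,
    stoichiometric_matrix,
)

__all__ = [
    "SSATrajectory",
    "Histogram",
    "SSAEnsemble",
    "simulate",
    "stationary_histogram",
    "histogram_modes",
]


@dataclass
class SSATrajectory:
    """One SSA sample path: ``states[i]`` is held on ``[times[i], times[i+1])``."""

    times: np.ndarray  # entry time of each state; times[0] = 0
    states: np.ndarray  # (n_states, k) integer states
    t_end: float
    seed: int
    frozen: bool = False  # all propensities hit zero (absorbing state)
    N: float = 1.0

    @property
    def n_events(self) -> int:
        return len(self.times) - 1


def _total_rate_lambda(net: ReactionNetwork, params, N: float):
    """Compile a(n) = N·ν(n) as one fast scalar-math callable."""
    n_syms = sp.symbols(f"n0:{net.n_species}")
    sigma = reactant_matrix(net)
    rates = net.resolved_rates(params)
    conc = {sp.Symbol(s): n_syms[i] / N for i, s in enumerate(net.species)}
    exprs = []
    for j, rxn in enumerate(net.reactions):
        mu = rates[j].subs(conc)
        free = mu.free_symbols - set(n_syms)
        if free:
            raise NetworkError(f"unresolved rate symbols {sorted(map(str, free))}")
        expr = N * mu
        for z in range(net.n_species):
            for l in range(sigma[z, j]):
                expr *= (n_syms[z] - l) / N
        exprs.append(expr)
    return sp.lambdify(n_syms, exprs, modules="math")


def simulate(
    net: ReactionNetwork,
    n0: Sequence[int],
    t_max: float,
    seed: int,
    params: Mapping[str, float] | None = None,
    N: float | None = None,
    max_events: int = 20_000_000,
) -> SSATrajectory:
    """Direct-method SSA run, reproducible for a fixed seed."""
    n0 = np.asarray(n0, dtype=np.int64)
    if n0.shape != (net.n_species,) or np.any(n0 < 0):
        raise NetworkError("n0 must be a non-negative integer state vector")
    Nval = float(N if N is not None else net.system_size)
    afunc = _total_rate_lambda(net, params, Nval)
    S = stoichiometric_matrix(net).entries
    S_cols = [tuple(int(v) for v in S[:, j]) for j in range(net.n_reactions)]
    m = net.n_reactions
    k = net.n_species

    rng = np.random.default_rng(seed)
    cap = 1 << 16
    times = np.empty(cap)
    states = np.empty((cap, k), dtype=np.int64)
    times[0] = 0.0
    states[0] = n0
    idx = 0
    t = 0.0
    n = tuple(int(v) for v in n0)
    frozen = False

    for _ in range(max_events):
        a = afunc(*n)
        atot = 0.0
        for aj in a:
            if aj < 0:
                raise NetworkError(f"negative propensity at state {n}")
            atot += aj
        if atot <= 0.0:
            frozen = True
            break
        t += rng.exponential(1.0 / atot)
        if t > t_max:
            t = t_max
            break
        u = rng.random() * atot
        acc = 0.0
        j = m - 1
        for jj in range(m):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        col = S_cols[j]
        n = tuple(n[z] + col[z] for z in range(k))
        idx += 1
        if idx >= cap:
            cap *= 2
            times = np.resize(times, cap)
            states = np.resize(states, (cap, k))
        times[idx] = t
        states[idx] = n
    else:
        t = times[idx]  # max_events reached; truncate at last event

    return SSATrajectory(
        times=times[: idx + 1].copy(),
        states=states[: idx + 1].copy(),
        t_end=float(min(t_max, t) if not frozen else t_max),
        seed=seed,
        frozen=frozen,
        N=Nval,
    )


@dataclass
class Histogram:
    """Normalized time-occupancy histogram over concentration space."""

    edges: tuple[np.ndarray, ...]
    mass: np.ndarray

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def bin_widths(self) -> tuple[float, ...]:
        return tuple(float(e[1] - e[0]) for e in self.edges)


def _aligned_edges(lo: float, hi: float, bins: int, N: float) -> np.ndarray:
    """Half-open bin edges aligned to multiples of 1/N covering [lo, hi].

    Edges are integer multiples of 1/N computed as ``k/N`` so that they
    compare exactly with concentrations ``n/N`` (no off-by-one-ulp bin
    misassignment).
    """
    width_int = max(1, round((hi - lo) / bins * N))
    start_int = int(np.floor(lo * N))
    n_bins = int(np.ceil((hi * N - start_int) / width_int))
    return (start_int + width_int * np.arange(n_bins + 1)) / N


def stationary_histogram(
    traj: SSATrajectory,
    burn_in: float,
    bins: int | Sequence[int] = 50,
    ranges: Sequence[tuple[float, float]] | None = None,
) -> Histogram:
    """Time-weighted occupancy histogram of x = n/N after ``burn_in``."""
    if burn_in >= traj.t_end:
        raise ValueError(f"burn_in {burn_in} must be < t_end {traj.t_end}")
    t0 = np.asarray(traj.times)
    t1 = np.append(t0[1:], traj.t_end)
    weights = np.clip(t1, burn_in, traj.t_end) - np.clip(t0, burn_in, traj.t_end)
    keep = weights > 0
    x = traj.states[keep] / traj.N
    weights = weights[keep]

    k = traj.states.shape[1]
    if isinstance(bins, int):
        bins = [bins] * k
    if ranges is None:
        ranges = [(float(x[:, i].min()), float(x[:, i].max()) + 1.0 / traj.N) for i in range(k)]
    edges = tuple(
        _aligned_edges(lo, hi, b, traj.N) for (lo, hi), b in zip(ranges, bins)
    )
    mass, _ = np.histogramdd(x, bins=edges, weights=weights)
    total = mass.sum()
    if total <= 0:
        raise ValueError("no occupancy mass inside the histogram range")
    return Histogram(edges=edges, mass=mass / total)


def histogram_modes(
    hist: Histogram,
    smoothing: float = 0.0,
    prominence: float = 0.05,
) -> list[tuple[np.ndarray, float]]:
    """Local maxima of the (optionally kernel-smoothed) histogram.

    A bin is a mode when it is a strict neighborhood maximum and its mass
    exceeds ``prominence`` times the global maximum.  Returned sorted by
    mass, descending; each entry is (bin-center coordinates, mass).
    """
    mass = hist.mass
    if smoothing > 0:
        mass = gaussian_filter(mass, sigma=smoothing, mode="nearest")
    peak = float(mass.max())
    if peak <= 0:
        return []
    local_max = mass >= maximum_filter(mass, size=3, mode="nearest")
    # break plateaus: require strictly greater than at least one neighbor
    strict = mass > 0
    cand = local_max & strict & (mass > prominence * peak)
    centers = hist.centers
    modes = []
    for idx in np.argwhere(cand):
        loc = np.array([centers[d][i] for d, i in enumerate(idx)])
        modes.append((loc, float(mass[tuple(idx)])))
    # deduplicate flat plateaus of equal mass: keep the first of adjacent bins
    modes.sort(key=lambda m: -m[1])
    return modes


@dataclass
class SSAEnsemble:
    """A set of SSA runs with their pooled stationary histogram."""

    trajectories: list[SSATrajectory]
    seed: int
    burn_in: float
    histogram: Histogram | None = None

    @classmethod
    def run(
        cls,
        net: ReactionNetwork,
        n0: Sequence[int],
        t_max: float,
        n_traj: int = 1,
        seed: int = 0,
        burn_in: float = 0.0,
        bins: int | Sequence[int] = 50,
        ranges: Sequence[tuple[float, float]] | None = None,
        params: Mapping[str, float] | None = None,
        N: float | None = None,
    ) -> "SSAEnsemble":
        ss = np.random.SeedSequence(seed)
        trajs = [
            simulate(net, n0, t_max, int(child.generate_state(1)[0]), params=params, N=N)
            for child in ss.spawn(n_traj)
        ]
        # pool: histogram each trajectory on shared edges, weight by observed time
        first = stationary_histogram(trajs[0], burn_in, bins=bins, ranges=ranges)
        if ranges is None:
            ranges = [(e[0], e[-1]) for e in first.edges]
        total_mass = np.zeros_like(first.mass)
        for traj in trajs:
            h = stationary_histogram(traj, burn_in, bins=bins, ranges=ranges)
            total_mass += h.mass * (traj.t_end - burn_in)
        total_mass /= total_mass.sum()
        return cls(trajs, seed, burn_in, Histogram(first.edges, total_mass))
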