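"""Built-in fixture models.

``foraging_colony``: two ant species recruiting each other between food
sources (rate r) and switching spontaneously (rate eps); the total number
of ants is conserved, and behavior is governed by N_C = r/eps.

``rosenzweig_macarthur``: predator-prey dynamics with logistic prey
competition, a Holling type-II functional response, predator death, and
small immigration flows that prevent spontaneous extinctions.  The default
parameter set yields a stable spiral; the ``limit_cycle`` overrides
(delta=0.1, beta=0.9) yield a limit cycle.
"""

from __future__ import annotations

from typing import Mapping

from .fields import FieldModel
from .reaction_network import ReactionNetwork, parse_network

__all__ = [
    "FIXTURES",
    "RM_STABLE_PARAMS",
    "RM_LIMIT_CYCLE_OVERRIDES",
    "fixture",
    "fixture_network",
    "effective_parameters",
]

_FORAGING_TEXT = """\
species: [X1, X2]
parameters: {r: 7.5, eps: 0.01}
reactions:
  - "X1 + X2 -> 2 X1 @ r"
  - "X1 + X2 -> 2 X2 @ r"
  - "X1 -> X2 @ eps"
  - "X2 -> X1 @ eps"
system_size: 1000
"""

RM_STABLE_PARAMS = {
    "A": 2.0 / 3.0,
    "d": 0.65,
    "c": 0.65,
    "b": 1.0,
    "q": 0.01,
    "delta": 0.2,
    "beta": 0.8,
}

RM_LIMIT_CYCLE_OVERRIDES = {"delta": 0.1, "beta": 0.9}

_RM_TEXT = """\
species: [X, Y]
parameters: {A: 0.6666666666666666, d: 0.65, c: 0.65, b: 1.0, q: 0.01, delta: 0.2, beta: 0.8}
reactions:
  - "X -> 2 X @ beta"
  - "X + X -> X @ delta"
  - "X + Y -> 2 Y @ d/(1 + A*X)"
  - "X + Y -> Y @ (b - d)/(1 + A*X)"
  - "Y -> 0 @ c"
  - "0 -> X @ q"
  - "0 -> Y @ q"
system_size: 80
"""

FIXTURES = {
    "foraging_colony": _FORAGING_TEXT,
    "rosenzweig_macarthur": _RM_TEXT,
}


def fixture_network(
    name: str, overrides: Mapping[str, float] | None = None
) -> ReactionNetwork:
    """A fixture network with optional parameter/``N`` overrides."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    net = parse_network(FIXTURES[name])
    overrides = dict(overrides or {})
    N = overrides.pop("N", None)
    if overrides or N is not None:
        unknown = set(overrides) - set(net.parameters)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)} for fixture {name!r}")
        net = ReactionNetwork(
            species=net.species,
            reactions=net.reactions,
            system_size=float(N) if N is not None else net.system_size,
            parameters={**net.parameters, **overrides},
        )
    return net


def fixture(
    name: str,
    overrides: Mapping[str, float] | None = None,
    derivative_policy: str = "symbolic",
) -> tuple[ReactionNetwork, FieldModel]:
    """Network plus compiled field model for a named fixture."""
    net = fixture_network(name, overrides)
    return net, FieldModel.from_network(net, derivative_policy=derivative_policy)


def effective_parameters(net: ReactionNetwork) -> dict[str, float]:
    """Derived control quantities of a fixture.

    Foraging colony: ``N_C = r/eps``.  Rosenzweig-MacArthur: ``kappa =
    A*c/d`` and ``eps_eff = delta*c/(beta*d)``.
    """
    p = net.parameters
    if {"r", "eps"} <= set(p):
        return {"N_C": p["r"] / p["eps"]}
    if {"A", "c", "d", "delta", "beta"} <= set(p):
        return {
            "kappa": p["A"] * p["c"] / p["d"],
            "eps_eff": p["delta"] * p["c"] / (p["beta"] * p["d"]),
        }
    raise ValueError("network does not match any known fixture parameterization")
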