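"""Reaction networks: parsing, stoichiometry, propensities, conservation laws.

A network is a list of species, a list of reactions written in the grammar

    reactants -> products @ rate

where each side is ``0`` (empty) or a ``+``-separated list of terms with
optional integer stoichiometric prefixes (``X1 + X2 -> 2 X1 @ r``), and a
system size ``N``.  Rates may be numbers or symbolic expressions over the
declared parameters and species names; a species name inside a rate
expression stands for its concentration ``n/N``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "NetworkError",
    "ParseError",
    "Reaction",
    "ReactionNetwork",
    "StoichiometricMatrix",
    "parse_network",
    "parse_reaction",
    "serialize_network",
    "stoichiometric_matrix",
    "propensities",
    "conservation_laws",
]

_NAME_RE = re.compile(r"^[A-Za-z_]\w*$")
_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_]\w*)\s*$")
_EMPTY_TOKENS = {"", "0", "∅"}


class NetworkError(ValueError):
    """Invalid reaction network (validation failure)."""


class ParseError(NetworkError):
    """Malformed model text; carries a line number when one is known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _as_rate(rate, allowed: set[str] | None = None) -> sp.Expr:
    """Coerce a rate to a sympy expression and validate it."""
    if isinstance(rate, str):
        # force every identifier to a plain Symbol so that names like
        # "beta" or "gamma" are not captured by sympy builtins
        names = set(re.findall(r"[A-Za-z_]\w*", rate)) | set(allowed or set())
        local = {name: sp.Symbol(name) for name in names}
        try:
            expr = sp.parse_expr(rate, local_dict=local)
        except Exception as exc:  # sympy raises a zoo of error types
            raise ParseError(f"cannot parse rate {rate!r}: {exc}") from exc
    else:
        expr = sp.sympify(rate)
    if allowed is not None:
        unknown = {str(s) for s in expr.free_symbols} - allowed
        if unknown:
            raise NetworkError(
                f"rate {sp.sstr(expr)!r} uses undeclared names: {sorted(unknown)}"
            )
    if expr.is_number:
        val = float(expr)
        if not val > 0:
            raise NetworkError(f"rate must be positive, got {val}")
    return expr


@dataclass(frozen=True)
class Reaction:
    """One reaction with reactant/product stoichiometries and a rate.

    ``reactants`` and ``products`` map species names to non-negative integer
    coefficients; ``rate`` is a positive number or a symbolic expression.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: sp.Expr
    label: str = ""

    def __post_init__(self):
        for side_name, side in (("reactants", self.reactants), ("products", self.products)):
            clean = {}
            for name, coeff in side.items():
                if int(coeff) != coeff or coeff < 0:
                    raise NetworkError(
                        f"{side_name} coefficient for {name} must be a non-negative "
                        f"integer, got {coeff!r}"
                    )
                if coeff > 0:
                    clean[str(name)] = int(coeff)
            object.__setattr__(self, side_name, clean)
        if not self.reactants and not self.products:
            raise NetworkError("reaction must have at least one reactant or product")
        object.__setattr__(self, "rate", _as_rate(self.rate))

    @property
    def species(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    def order(self) -> int:
        return sum(self.reactants.values())


def parse_reaction(text: str, line: int | None = None) -> Reaction:
    """Parse one ``reactants -> products @ rate`` string."""
    if "@" not in text:
        raise ParseError(f"missing '@ rate' in {text!r}", line)
    body, rate = text.rsplit("@", 1)
    if "->" not in body:
        raise ParseError(f"missing '->' in {text!r}", line)
    lhs, rhs = body.split("->", 1)

    def parse_side(side: str) -> dict[str, int]:
        side = side.strip()
        if side in _EMPTY_TOKENS:
            return {}
        out: dict[str, int] = {}
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if m is None:
                raise ParseError(f"bad term {term.strip()!r} in {text!r}", line)
            coeff = int(m.group(1) or 1)
            out[m.group(2)] = out.get(m.group(2), 0) + coeff
        return out

    try:
        return Reaction(parse_side(lhs), parse_side(rhs), rate.strip(), label=text.strip())
    except ParseError:
        raise
    except NetworkError as exc:
        raise ParseError(str(exc), line) from exc


@dataclass(frozen=True)
class ReactionNetwork:
    """A validated reaction network: the single source of truth.

    Attributes
    ----------
    species : ordered tuple of unique species names
    reactions : ordered tuple of :class:`Reaction`
    system_size : positive real N (reactor volume / total-reactant scale)
    parameters : mapping of parameter name to numeric value, used to resolve
        symbolic rates
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    system_size: float
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(str(s) for s in self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "parameters", dict(self.parameters))
        if len(set(self.species)) != len(self.species):
            raise NetworkError("species names must be unique")
        for name in self.species:
            if not _NAME_RE.match(name):
                raise NetworkError(f"invalid species name {name!r}")
        if not self.system_size > 0:
            raise NetworkError("system_size must be positive")
        declared = set(self.species)
        allowed = declared | set(self.parameters)
        for rxn in self.reactions:
            missing = rxn.species - declared
            if missing:
                raise NetworkError(f"undeclared species {sorted(missing)} in {rxn.label!r}")
            # re-validate the rate against the declared name set
            _as_rate(rxn.rate, allowed)
            resolved = rxn.rate.subs({sp.Symbol(k): v for k, v in self.parameters.items()})
            if resolved.is_number and not float(resolved) > 0:
                raise NetworkError(f"non-positive rate in {rxn.label!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def resolved_rates(self, overrides: Mapping[str, float] | None = None) -> list[sp.Expr]:
        """Rates with the parameter table (plus overrides) substituted in."""
        table = {**self.parameters, **(overrides or {})}
        subs = {sp.Symbol(k): v for k, v in table.items()}
        return [rxn.rate.subs(subs) for rxn in self.reactions]


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Integer k×m matrix S with S_ij = products_ij − reactants_ij."""

    entries: np.ndarray
    species: tuple[str, ...]

    def __post_init__(self):
        arr = np.asarray(self.entries, dtype=np.int64)
        object.__setattr__(self, "entries", arr)
        if arr.ndim != 2 or arr.shape[0] != len(self.species):
            raise NetworkError("stoichiometric matrix shape does not match species")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def stoichiometric_matrix(net: ReactionNetwork) -> StoichiometricMatrix:
    """Net change per reaction: column j is products − reactants."""
    k, m = net.n_species, net.n_reactions
    S = np.zeros((k, m), dtype=np.int64)
    for j, rxn in enumerate(net.reactions):
        for name, coeff in rxn.reactants.items():
            S[net.species_index(name), j] -= coeff
        for name, coeff in rxn.products.items():
            S[net.species_index(name), j] += coeff
    return StoichiometricMatrix(S, net.species)


def reactant_matrix(net: ReactionNetwork) -> np.ndarray:
    """k×m matrix of reactant coefficients (σ)."""
    k, m = net.n_species, net.n_reactions
    sigma = np.zeros((k, m), dtype=np.int64)
    for j, rxn in enumerate(net.reactions):
        for name, coeff in rxn.reactants.items():
            sigma[net.species_index(name), j] = coeff
    return sigma


def propensities(
    net: ReactionNetwork,
    counts: Sequence[int],
    params: Mapping[str, float] | None = None,
    N: float | None = None,
) -> np.ndarray:
    """Per-reaction stochastic rates at integer state ``counts``.

    The propensity of reaction j is the rate times the combinatorial
    probability of the reactant molecules to meet,
    ``rate * prod_z N**(-sigma_zj) * n_z!/(n_z - sigma_zj)!``,
    evaluated with falling factorials.  It vanishes whenever any reactant
    count falls short of its stoichiometric coefficient.
    """
    n = np.asarray(counts)
    if n.shape != (net.n_species,):
        raise NetworkError(f"expected {net.n_species} counts, got shape {n.shape}")
    if np.any(n < 0):
        raise NetworkError("counts must be non-negative")
    if not np.issubdtype(n.dtype, np.integer):
        if not np.allclose(n, np.round(n)):
            raise NetworkError("counts must be integers")
        n = np.round(n).astype(np.int64)
    Nval = float(N if N is not None else net.system_size)
    rates = net.resolved_rates(params)
    x_subs = {sp.Symbol(s): n[i] / Nval for i, s in enumerate(net.species)}
    nu = np.zeros(net.n_reactions)
    for j, rxn in enumerate(net.reactions):
        mu = rates[j].subs(x_subs)
        if not mu.is_number:
            raise NetworkError(f"unresolved rate {sp.sstr(mu)!r} in {rxn.label!r}")
        val = float(mu)
        for name, sigma in rxn.reactants.items():
            nz = int(n[net.species_index(name)])
            if nz < sigma:
                val = 0.0
                break
            val *= math.perm(nz, sigma) / Nval**sigma
        nu[j] = val
    return nu


def conservation_laws(S: StoichiometricMatrix | np.ndarray) -> list[np.ndarray]:
    """Integer basis of the left null space {c : cᵀS = 0}.

    Computed over the rationals and scaled to coprime integers, so the
    identity cᵀS = 0 holds exactly.  Returns an empty list when S has full
    row rank.
    """
    entries = S.entries if isinstance(S, StoichiometricMatrix) else np.asarray(S)
    M = sp.Matrix(entries.tolist())
    laws = []
    for vec in M.T.nullspace():
        fracs = [Fraction(sp.Rational(v).p, sp.Rational(v).q) for v in vec]
        denom = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
        ints = [int(f * denom) for f in fracs]
        g = math.gcd(*(abs(i) for i in ints if i != 0))
        ints = [i // g for i in ints]
        lead = next((i for i in ints if i != 0), 1)
        if lead < 0:
            ints = [-i for i in ints]
        laws.append(np.array(ints, dtype=np.int64))
    return laws


# ---------------------------------------------------------------------------
# Model file dialect


def parse_network(text: str) -> ReactionNetwork:
    """Parse a YAML model document.

    Expected keys: ``species`` (list of names), ``parameters`` (optional
    name→number map), ``reactions`` (list of grammar strings), and
    ``system_size`` (positive number).
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise ParseError(str(exc), None if mark is None else mark.line + 1) from exc
    if not isinstance(doc, dict):
        raise ParseError("model document must be a mapping")
    unknown = set(doc) - {"species", "parameters", "reactions", "system_size"}
    if unknown:
        raise ParseError(f"unknown keys: {sorted(unknown)}")

    species = doc.get("species") or []
    params = doc.get("parameters") or {}
    if not isinstance(params, dict):
        raise ParseError("'parameters' must be a mapping")
    raw_reactions = doc.get("reactions") or []
    if "system_size" not in doc:
        raise ParseError("missing 'system_size'")

    lines = text.splitlines()

    def line_of(snippet: str) -> int | None:
        for i, ln in enumerate(lines, start=1):
            if snippet.strip() and snippet.strip() in ln:
                return i
        return None

    reactions = []
    for raw in raw_reactions:
        if not isinstance(raw, str):
            raise ParseError(f"reaction entries must be strings, got {raw!r}")
        reactions.append(parse_reaction(raw, line=line_of(raw)))

    return ReactionNetwork(
        species=tuple(species),
        reactions=tuple(reactions),
        system_size=float(doc["system_size"]),
        parameters={str(k): float(v) for k, v in params.items()},
    )


def _format_side(side: Mapping[str, int]) -> str:
    if not side:
        return "0"
    return " + ".join(f"{c} {s}" if c != 1 else s for s, c in side.items())


def serialize_network(net: ReactionNetwork) -> str:
    """Write the same YAML dialect that :func:`parse_network` reads."""
    doc = {
        "species": list(net.species),
        "parameters": {k: float(v) for k, v in net.parameters.items()},
        "reactions": [
            f"{_format_side(r.reactants)} -> {_format_side(r.products)} @ {sp.sstr(r.rate)}"
            for r in net.reactions
        ],
        "system_size": float(net.system_size),
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
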