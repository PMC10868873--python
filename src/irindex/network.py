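"""Reaction-kinetic network representation.

A network holds the stoichiometric matrix ``N`` (n species x M reactions) and
one symbolic rate law per reaction, so that the ODE right-hand side is

    f(x; p) = N @ alpha(x; p),

with ``alpha`` the vector of reaction rates.  Rate laws are stored as sympy
expressions and differentiated analytically; the compiled Jacobian is exact,
which the downstream sensitivity and classification machinery relies on.

Units follow the nM / min convention throughout; unit conversion is the
caller's responsibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

__all__ = [
    "NetworkValidationError",
    "RateLawParseError",
    "ReactionNetwork",
    "build_network",
    "load_network",
    "serialize",
]


class NetworkValidationError(ValueError):
    """A network description is structurally invalid."""


class RateLawParseError(ValueError):
    """A rate-law expression could not be parsed."""


_ALLOWED_FUNCS = {
    # constructors parse_expr needs for literals and auto-created symbols
    "Symbol": sp.Symbol,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tanh": sp.tanh,
    "Abs": sp.Abs,
    "Min": sp.Min,
    "Max": sp.Max,
}


def _parse_rate_law(expr: str, symbols: Mapping[str, sp.Symbol], where: str) -> sp.Expr:
    try:
        parsed = parse_expr(
            expr,
            local_dict=dict(symbols),
            global_dict=dict(_ALLOWED_FUNCS),
            transformations=standard_transformations,
            evaluate=True,
        )
    except Exception as exc:  # sympy raises a zoo of error types
        raise RateLawParseError(f"cannot parse rate law of {where}: {expr!r} ({exc})") from exc
    free = {str(s) for s in parsed.free_symbols}
    unknown = free - set(symbols)
    if unknown:
        raise NetworkValidationError(
            f"rate law of {where} references unknown identifiers {sorted(unknown)}"
        )
    return parsed


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: dict[str, float]  # species -> stoichiometric coefficient (>0)
    products: dict[str, float]
    rate_law: str


class ReactionNetwork:
    """Compiled reaction network with analytic right-hand side and Jacobian.

    Parameters are bound at compile time; :meth:`with_params` returns a new
    network with a modified parameter vector (used e.g. for unit-invariance
    checks and scenario definitions).
    """

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        params: Mapping[str, float],
        param_units: Mapping[str, str] | None = None,
        initial_state: Sequence[float] | None = None,
        metadata: Mapping[str, str] | None = None,
    ):
        self.species = tuple(species)
        if len(set(self.species)) != len(self.species):
            raise NetworkValidationError("species names must be unique")
        if len(self.species) < 2:
            raise NetworkValidationError("a network needs at least two species")
        if not reactions:
            raise NetworkValidationError("a network needs at least one reaction")
        self.reactions = tuple(reactions)
        self.params = dict(params)
        self.param_units = dict(param_units or {})
        self.metadata = dict(metadata or {})
        self.n = len(self.species)
        self.M = len(self.reactions)
        self._index = {name: k for k, name in enumerate(self.species)}

        if initial_state is None:
            initial_state = np.zeros(self.n)
        self.initial_state = np.asarray(initial_state, dtype=float)
        if self.initial_state.shape != (self.n,):
            raise NetworkValidationError("initial state length must match species count")

        # stoichiometric matrix and reactant / product index sets
        N = np.zeros((self.n, self.M))
        reactant_sets: list[frozenset[int]] = []
        product_sets: list[frozenset[int]] = []
        for mu, rxn in enumerate(self.reactions):
            for side, sign in ((rxn.reactants, -1.0), (rxn.products, +1.0)):
                for name, coeff in side.items():
                    if name not in self._index:
                        raise NetworkValidationError(
                            f"reaction {rxn.id!r} references undeclared species {name!r}"
                        )
                    N[self._index[name], mu] += sign * coeff
            reactant_sets.append(frozenset(self._index[s] for s in rxn.reactants))
            product_sets.append(frozenset(self._index[s] for s in rxn.products))
        self.stoich = N
        self.reactant_sets = tuple(reactant_sets)
        self.product_sets = tuple(product_sets)

        self._compile()

    # ------------------------------------------------------------------ #
    def _compile(self) -> None:
        x_syms = [sp.Symbol(s) for s in self.species]
        p_syms = {name: sp.Symbol(name) for name in self.params}
        symbols = {str(s): s for s in x_syms}
        overlap = set(symbols) & set(p_syms)
        if overlap:
            raise NetworkValidationError(f"names used for both species and parameters: {sorted(overlap)}")
        symbols.update(p_syms)

        rate_exprs = []
        for rxn in self.reactions:
            expr = _parse_rate_law(rxn.rate_law, symbols, f"reaction {rxn.id!r}")
            rate_exprs.append(expr)
        self.rate_exprs = tuple(rate_exprs)

        subs = {p_syms[name]: sp.Float(value) for name, value in self.params.items()}
        bound = [e.subs(subs) for e in rate_exprs]
        drate = [[sp.diff(e, xs) for xs in x_syms] for e in bound]

        self._rate_fn = sp.lambdify(x_syms, bound, modules="numpy")
        self._drate_fn = sp.lambdify(x_syms, drate, modules="numpy")

        # structural Jacobian sparsity: (k,l) can be nonzero only if species l
        # enters the rate law of a reaction with nonzero stoichiometry for k
        pattern = np.zeros((self.n, self.n), dtype=bool)
        for mu, expr in enumerate(bound):
            deps = [self._index[str(s)] for s in expr.free_symbols if str(s) in self._index]
            rows = np.nonzero(self.stoich[:, mu])[0]
            for k in rows:
                pattern[k, deps] = True
        self.jacobian_sparsity = pattern

        # species with non-integer powers in some rate law need clipping of
        # solver-induced tiny negatives before evaluation
        self._clip_before_rates = any(
            isinstance(a, sp.Pow) and not a.exp.is_integer
            for e in bound
            for a in sp.preorder_traversal(e)
        )

    # ------------------------------------------------------------------ #
    def index(self, name: str) -> int:
        """Index of a species by name."""
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}; known: {list(self.species)}") from None

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"state vector must have length {self.n}, got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("state vector contains non-finite entries")
        if self._clip_before_rates:
            x = np.clip(x, 0.0, None)
        return x

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Reaction-rate vector alpha(x; p), shape (M,)."""
        x = self._prep(x)
        return np.asarray(self._rate_fn(*x), dtype=float)

    def rhs(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """f(x; p) = N @ alpha(x; p); ``mask`` deactivates reactions (False = removed)."""
        r = self.rates(x)
        if mask is not None:
            r = r * mask
        return self.stoich @ r

    def drates_dx(self, x: np.ndarray) -> np.ndarray:
        x = self._prep(x)
        return np.asarray(self._drate_fn(*x), dtype=float)

    def jac(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Analytic Jacobian d f / d x, shape (n, n)."""
        dr = self.drates_dx(x)
        if mask is not None:
            dr = dr * mask[:, None]
        return self.stoich @ dr

    # ------------------------------------------------------------------ #
    def reaction_mask(self, targets: Iterable[int], involve: str) -> np.ndarray:
        """Boolean mask of reactions surviving removal of ``targets``.

        involve='reactant'  removes reactions consuming a target (partial neglect);
        involve='any'       removes reactions consuming or producing one (complete
        neglect).
        """
        targets = set(targets)
        keep = np.ones(self.M, dtype=bool)
        for mu in range(self.M):
            involved = set(self.reactant_sets[mu])
            if involve == "any":
                involved |= set(self.product_sets[mu])
            if involved & targets:
                keep[mu] = False
        return keep

    def with_params(self, params: Mapping[str, float]) -> "ReactionNetwork":
        new = dict(self.params)
        new.update(params)
        return ReactionNetwork(
            self.species,
            self.reactions,
            new,
            self.param_units,
            self.initial_state,
            self.metadata,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReactionNetwork(n={self.n}, M={self.M}, species={list(self.species)})"


# ---------------------------------------------------------------------- #
# native JSON schema
# ---------------------------------------------------------------------- #

def build_network(spec: Mapping) -> ReactionNetwork:
    """Build a validated network from a native schema record.

    The schema is a JSON-style mapping with keys ``species`` (name,
    initial_value), ``parameters`` (name, value, unit), ``reactions`` (id,
    reactants/products with stoichiometry, rate_law) and optional ``metadata``.
    """
    try:
        species_rec = spec["species"]
        reactions_rec = spec["reactions"]
    except KeyError as exc:
        raise NetworkValidationError(f"network record is missing key {exc}") from exc
    species = [rec["name"] for rec in species_rec]
    x0 = [float(rec.get("initial_value", 0.0)) for rec in species_rec]
    params = {rec["name"]: float(rec["value"]) for rec in spec.get("parameters", [])}
    units = {rec["name"]: rec.get("unit", "") for rec in spec.get("parameters", [])}

    def side(rec, key):
        out: dict[str, float] = {}
        for item in rec.get(key, []):
            out[item["species"]] = out.get(item["species"], 0.0) + float(
                item.get("stoichiometry", 1.0)
            )
        return out

    reactions = [
        Reaction(
            id=str(rec.get("id", f"r{i + 1}")),
            reactants=side(rec, "reactants"),
            products=side(rec, "products"),
            rate_law=rec["rate_law"],
        )
        for i, rec in enumerate(reactions_rec)
    ]
    return ReactionNetwork(
        species,
        reactions,
        params,
        units,
        x0,
        spec.get("metadata"),
    )


def serialize(net: ReactionNetwork) -> dict:
    """Native-schema record for ``net`` (round-trips through :func:`build_network`)."""
    return {
        "species": [
            {"name": s, "initial_value": float(v)}
            for s, v in zip(net.species, net.initial_state)
        ],
        "parameters": [
            {"name": k, "value": v, "unit": net.param_units.get(k, "")}
            for k, v in net.params.items()
        ],
        "reactions": [
            {
                "id": rxn.id,
                "reactants": [
                    {"species": s, "stoichiometry": c} for s, c in rxn.reactants.items()
                ],
                "products": [
                    {"species": s, "stoichiometry": c} for s, c in rxn.products.items()
                ],
                "rate_law": rxn.rate_law,
            }
            for rxn in net.reactions
        ],
        "metadata": dict(net.metadata) or {"time_unit": "min", "concentration_unit": "nM"},
    }


def load_network(path) -> ReactionNetwork:
    """Load a network from a native-schema JSON file."""
    with open(path) as fh:
        return build_network(json.load(fh))
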