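"""Minimal SBML Level 2/3 import.

Covers the subset needed for reaction-kinetic index analysis: species with
initial amounts or concentrations, global and reaction-local parameters, and
kinetic laws given as MathML expressions over +, -, *, /, powers and a few
elementary functions.  Compartment size dynamics, events, rules and units are
out of scope; initial amounts are taken at face value as concentrations in
the model's own unit convention.

Reversible reactions are split into a forward and a backward irreversible
reaction only when the kinetic law is recognisably a difference of two
nonnegatively-signed term groups (e.g. ``kf*A*B - kr*C``); otherwise the
reaction is kept as a single signed rate and the consuming-species set used
by the neglect modifications is widened to reactants plus modifiers.
"""

from __future__ import annotations

from typing import Mapping

import sympy as sp
from lxml import etree

from .network import NetworkValidationError, Reaction, ReactionNetwork

__all__ = ["read_sbml", "SBMLImportError"]


class SBMLImportError(ValueError):
    """The SBML document cannot be interpreted."""


_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


_BINARY = {"divide": "/", "power": "^"}
_NARY = {"plus": "+", "times": "*"}
_FUNCS = {"exp", "ln", "log", "root", "abs"}


def _math_to_infix(node, rename: Mapping[str, str]) -> str:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLImportError("expected a single expression under <math>")
        return _math_to_infix(children[0], rename)
    if tag == "ci":
        name = (node.text or "").strip()
        return rename.get(name, name)
    if tag == "cn":
        sub = node.findall(f"{{{_MATHML_NS}}}sep")
        if sub:  # rational / e-notation forms
            parts = [t.strip() for t in node.itertext() if t.strip()]
            if node.get("type") == "e-notation":
                return f"({parts[0]}e{parts[1]})"
            return f"({parts[0]}/{parts[1]})"
        return (node.text or "").strip()
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_math_to_infix(c, rename) for c in children[1:]]
        if op in _NARY:
            return "(" + f" {_NARY[op]} ".join(args) + ")"
        if op == "minus":
            if len(args) == 1:
                return f"(-{args[0]})"
            return f"({args[0]} - {args[1]})"
        if op in _BINARY:
            if len(args) != 2:
                raise SBMLImportError(f"<{op}> expects two operands")
            symbol = _BINARY[op]
            if symbol == "^":
                return f"({args[0]})**({args[1]})"
            return f"({args[0]} {symbol} {args[1]})"
        if op == "ln":
            return f"log({args[0]})"
        if op in _FUNCS:
            return f"{op}({', '.join(args)})"
        raise SBMLImportError(f"unsupported MathML operator <{op}>")
    raise SBMLImportError(f"unsupported MathML element <{tag}>")


def _split_reversible(expr_str: str, symbols) -> tuple[str, str] | None:
    """Split ``kf*... - kr*...`` into (forward, backward) infix strings."""
    try:
        expr = sp.sympify(expr_str, locals={s: sp.Symbol(s) for s in symbols})
    except Exception:
        return None
    expr = sp.expand(expr)
    terms = expr.as_ordered_terms()
    pos = [t for t in terms if not t.could_extract_minus_sign()]
    neg = [-t for t in terms if t.could_extract_minus_sign()]
    if pos and neg:
        return str(sp.Add(*pos)), str(sp.Add(*neg))
    return None


def read_sbml(path) -> ReactionNetwork:
    """Parse an SBML file into a :class:`ReactionNetwork`."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    model = next((c for c in root if _local(c.tag) == "model"), None)
    if model is None:
        raise SBMLImportError("no <model> element found")

    def section(name):
        for c in model:
            if _local(c.tag) == name:
                return list(c)
        return []

    species_order: list[str] = []
    x0: list[float] = []
    boundary: set[str] = set()
    for sp_el in section("listOfSpecies"):
        sid = sp_el.get("id")
        species_order.append(sid)
        amount = sp_el.get("initialConcentration") or sp_el.get("initialAmount") or "0"
        x0.append(float(amount))
        if sp_el.get("boundaryCondition") in ("true", "1"):
            boundary.add(sid)

    params: dict[str, float] = {}
    units: dict[str, str] = {}
    for p_el in section("listOfParameters"):
        params[p_el.get("id")] = float(p_el.get("value", "0"))
        units[p_el.get("id")] = p_el.get("units", "")
    # compartments enter kinetic laws as named sizes
    for c_el in section("listOfCompartments"):
        params[c_el.get("id")] = float(c_el.get("size", c_el.get("volume", "1") or "1"))
        units[c_el.get("id")] = "compartment_size"

    reactions: list[Reaction] = []
    for r_el in section("listOfReactions"):
        rid = r_el.get("id") or f"r{len(reactions) + 1}"
        reversible = r_el.get("reversible", "true") in ("true", "1")
        reactants: dict[str, float] = {}
        products: dict[str, float] = {}
        modifiers: list[str] = []
        kinetic = None
        rename: dict[str, str] = {}
        for part in r_el:
            ptag = _local(part.tag)
            if ptag in ("listOfReactants", "listOfProducts"):
                target = reactants if ptag == "listOfReactants" else products
                for ref in part:
                    name = ref.get("species")
                    if name in boundary:
                        continue  # boundary species are fixed: no stoichiometric change
                    target[name] = target.get(name, 0.0) + float(
                        ref.get("stoichiometry", "1")
                    )
            elif ptag == "listOfModifiers":
                modifiers = [ref.get("species") for ref in part]
            elif ptag == "kineticLaw":
                for sub in part:
                    stag = _local(sub.tag)
                    if stag in ("listOfParameters", "listOfLocalParameters"):
                        for p_el in sub:
                            pid = p_el.get("id")
                            scoped = f"{rid}__{pid}" if pid in params or pid in species_order else pid
                            rename[pid] = scoped
                            params[scoped] = float(p_el.get("value", "0"))
                            units[scoped] = p_el.get("units", "")
                    elif stag == "math":
                        kinetic = sub
                if kinetic is None:
                    raise SBMLImportError(f"reaction {rid!r} has a kineticLaw without <math>")
        if kinetic is None:
            raise SBMLImportError(f"reaction {rid!r} has no kinetic law")
        expr = _math_to_infix(kinetic, rename)

        split = None
        if reversible:
            split = _split_reversible(expr, set(species_order) | set(params))
        if split is not None:
            fwd, bwd = split
            reactions.append(Reaction(f"{rid}_fwd", reactants, products, fwd))
            reactions.append(Reaction(f"{rid}_bwd", products, reactants, bwd))
        else:
            if reversible:
                # keep one signed rate; widen the consuming set to modifiers too
                for m in modifiers:
                    reactants.setdefault(m, 0.0)
            reactions.append(Reaction(rid, reactants, products, expr))

    if not species_order:
        raise SBMLImportError("model declares no species")
    try:
        return ReactionNetwork(
            species_order,
            reactions,
            params,
            units,
            x0,
            {"source": "sbml", "model_id": model.get("id", "")},
        )
    except NetworkValidationError as exc:
        raise SBMLImportError(f"imported model is invalid: {exc}") from exc
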