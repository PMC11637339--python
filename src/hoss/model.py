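"""Reaction-network models: loading, interrogation, parameter addressing, serialization.

A :class:`NetworkModel` is the shared in-memory container for every algorithm in
this package: mass-action or general kinetic-law ODE models with a species set
(some of which may be *buffered*, i.e. held constant), a reaction set with
arbitrary arithmetic rate laws, and local/global parameters.  Models are read
and written either as SBML (Level 2/3, kinetic laws required) or as the native
``hoss-model-1`` JSON dialect, which mirrors SBML semantics.

Tunable scalars are addressed by :class:`ParameterRef` paths:

* ``"<reaction_id>.<param_name>"`` — a local reaction parameter,
* ``"<species_id>.concInit"``     — an initial concentration,
* a bare name                      — a global parameter.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import sympy
from sympy.parsing.sympy_parser import (
    parse_expr,
    standard_transformations,
    convert_xor,
)

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "NetworkModel",
    "ParameterRef",
    "ModelFormatError",
    "ReferenceError_",
    "load_model",
    "write_model",
    "stoichiometric_matrix",
    "rate_dependencies",
    "get_parameter",
    "set_parameter",
    "models_equivalent",
]

_PARSE_TRANSFORMS = standard_transformations + (convert_xor,)


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or violates the format."""


class ReferenceError_(KeyError):
    """Raised when a parameter path does not resolve to exactly one scalar."""


class ExpressionError(ValueError):
    """Raised when a rate law cannot be parsed or differentiated."""


@dataclass
class SpeciesDef:
    id: str
    name: str = ""
    initial_conc: float = 0.0
    buffered: bool = False
    compartment: str = "cell"

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        if self.initial_conc < 0:
            raise ValueError(f"species {self.id}: initial_conc must be >= 0")


@dataclass
class ReactionDef:
    id: str
    reactant_stoich: Dict[str, int] = field(default_factory=dict)
    product_stoich: Dict[str, int] = field(default_factory=dict)
    modifiers: List[str] = field(default_factory=list)
    rate_law: str = "0"
    reversible: bool = False
    parameters: Dict[str, float] = field(default_factory=dict)


def _local_symbol(reaction_id: str, pname: str) -> sympy.Symbol:
    return sympy.Symbol(f"{reaction_id}__{pname}")


@dataclass
class NetworkModel:
    species: List[SpeciesDef] = field(default_factory=list)
    reactions: List[ReactionDef] = field(default_factory=list)
    global_parameters: Dict[str, float] = field(default_factory=dict)
    annotations: Dict[str, object] = field(default_factory=dict)

    # ---- lookups -------------------------------------------------------
    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def species_index(self) -> Dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise ReferenceError_(f"unknown species {sid!r}")

    def get_reaction(self, rid: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ReferenceError_(f"unknown reaction {rid!r}")

    def buffered_ids(self) -> Set[str]:
        return {s.id for s in self.species if s.buffered}

    def copy(self) -> "NetworkModel":
        return copy.deepcopy(self)

    # ---- symbolic rate laws -------------------------------------------
    def rate_expression(self, rid: str) -> sympy.Expr:
        """Parse a reaction's rate law into a sympy expression.

        Species keep their ids as symbols; local parameters are renamed to
        ``<rid>__<name>`` so that expressions from different reactions can
        be stacked into one ODE system without name clashes.
        """
        rxn = self.get_reaction(rid)
        local = {name: _local_symbol(rid, name) for name in rxn.parameters}
        names: Dict[str, sympy.Symbol] = {}
        for s in self.species:
            names[s.id] = sympy.Symbol(s.id)
        for g in self.global_parameters:
            names.setdefault(g, sympy.Symbol(g))
        names.update(local)
        try:
            expr = parse_expr(
                rxn.rate_law, local_dict=names, transformations=_PARSE_TRANSFORMS
            )
        except Exception as exc:  # pragma: no cover - message path
            raise ExpressionError(f"cannot parse rate law of {rid!r}: {exc}") from exc
        return expr

    def validate(self) -> None:
        sids = self.species_ids()
        if len(set(sids)) != len(sids):
            raise ModelFormatError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelFormatError("duplicate reaction ids")
        known = set(sids)
        for r in self.reactions:
            for sid in list(r.reactant_stoich) + list(r.product_stoich) + r.modifiers:
                if sid not in known:
                    raise ModelFormatError(
                        f"reaction {r.id}: unknown species {sid!r}"
                    )
            expr = self.rate_expression(r.id)
            allowed = (
                {sympy.Symbol(s) for s in sids}
                | {sympy.Symbol(g) for g in self.global_parameters}
                | {_local_symbol(r.id, p) for p in r.parameters}
            )
            extra = expr.free_symbols - allowed
            if extra:
                raise ModelFormatError(
                    f"reaction {r.id}: undefined names in rate law: "
                    + ", ".join(sorted(str(x) for x in extra))
                )
        # rate laws must evaluate finitely at a positive state
        rng = np.random.default_rng(0)
        state = {s.id: float(v) for s, v in zip(self.species, rng.uniform(0.1, 1.0, len(self.species)))}
        for r in self.reactions:
            v = _evaluate_rate(self, r.id, state)
            if not math.isfinite(v):
                raise ModelFormatError(
                    f"reaction {r.id}: rate law not finite at a positive state"
                )


# ---------------------------------------------------------------------------
# stoichiometry and dependencies
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: NetworkModel) -> np.ndarray:
    """Return S with S[i, j] = products_ij - reactants_ij, shape (#species, #reactions)."""
    idx = model.species_index()
    S = np.zeros((len(model.species), len(model.reactions)), dtype=int)
    for j, r in enumerate(model.reactions):
        for sid, n in r.reactant_stoich.items():
            S[idx[sid], j] -= int(n)
        for sid, n in r.product_stoich.items():
            S[idx[sid], j] += int(n)
    return S


def _evaluate_rate(model: NetworkModel, rid: str, state: Mapping[str, float]) -> float:
    rxn = model.get_reaction(rid)
    expr = model.rate_expression(rid)
    subs = {sympy.Symbol(s.id): state.get(s.id, s.initial_conc) for s in model.species}
    subs.update({sympy.Symbol(g): v for g, v in model.global_parameters.items()})
    subs.update({_local_symbol(rid, p): v for p, v in rxn.parameters.items()})
    return float(expr.evalf(subs=subs))


def rate_dependencies(model: NetworkModel, reaction_id: str) -> Set[str]:
    """Species whose concentration the reaction rate depends on.

    Computed symbolically (a partial derivative not identically zero), with a
    finite-difference fallback for expressions sympy cannot differentiate.
    Declared modifiers are always included; for reversible reactions the rate
    law carries both the forward and the backward term, so the union over both
    directions falls out of the single expression.
    """
    rxn = model.get_reaction(reaction_id)
    deps: Set[str] = set(rxn.modifiers)
    try:
        expr = model.rate_expression(reaction_id)
        for s in model.species:
            sym = sympy.Symbol(s.id)
            if sym in expr.free_symbols and sympy.diff(expr, sym) != 0:
                deps.add(s.id)
    except ExpressionError:
        deps |= _numeric_dependencies(model, reaction_id)
    return deps


def _numeric_dependencies(
    model: NetworkModel, reaction_id: str, n_states: int = 10, seed: int = 0
) -> Set[str]:
    """Finite-difference dependency probe at random positive states."""
    rng = np.random.default_rng(seed)
    deps: Set[str] = set()
    for _ in range(n_states):
        state = {s.id: float(rng.uniform(0.1, 2.0)) for s in model.species}
        base = _evaluate_rate(model, reaction_id, state)
        for s in model.species:
            if s.id in deps:
                continue
            bumped = dict(state)
            bumped[s.id] = state[s.id] * (1 + 1e-6) + 1e-9
            if not math.isclose(
                _evaluate_rate(model, reaction_id, bumped), base,
                rel_tol=1e-9, abs_tol=1e-12,
            ):
                deps.add(s.id)
    return deps


# ---------------------------------------------------------------------------
# parameter addressing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterRef:
    """Path addressing one tunable scalar in a model (see module docstring)."""

    path: str

    def _resolve(self, model: NetworkModel):
        if "." in self.path:
            head, tail = self.path.split(".", 1)
            if tail == "concInit":
                for s in model.species:
                    if s.id == head:
                        return ("species", s)
            for r in model.reactions:
                if r.id == head and tail in r.parameters:
                    return ("local", r, tail)
            raise ReferenceError_(f"parameter path {self.path!r} does not resolve")
        if self.path in model.global_parameters:
            return ("global", self.path)
        raise ReferenceError_(f"parameter path {self.path!r} does not resolve")


def get_parameter(model: NetworkModel, ref: ParameterRef) -> float:
    kind = ref._resolve(model)
    if kind[0] == "species":
        return kind[1].initial_conc
    if kind[0] == "local":
        return kind[1].parameters[kind[2]]
    return model.global_parameters[kind[1]]


def set_parameter_inplace(model: NetworkModel, ref: ParameterRef, value: float) -> None:
    """Mutating setter used in optimization hot loops (no model copy)."""
    kind = ref._resolve(model)
    if kind[0] == "species":
        if value < 0:
            raise ValueError(f"{ref.path}: initial_conc must be >= 0")
        kind[1].initial_conc = float(value)
    elif kind[0] == "local":
        kind[1].parameters[kind[2]] = float(value)
    else:
        model.global_parameters[kind[1]] = float(value)


def set_parameter(model: NetworkModel, ref: ParameterRef, value: float) -> NetworkModel:
    """Return a copy of the model with one scalar changed; nothing else moves."""
    out = model.copy()
    set_parameter_inplace(out, ref, value)
    return out


# ---------------------------------------------------------------------------
# native JSON dialect "hoss-model-1"
# ---------------------------------------------------------------------------

NATIVE_FORMAT_TAG = "hoss-model-1"


def _model_to_native(model: NetworkModel) -> dict:
    return {
        "format": NATIVE_FORMAT_TAG,
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "initial_conc": s.initial_conc,
                "buffered": s.buffered,
                "compartment": s.compartment,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": dict(r.reactant_stoich),
                "products": dict(r.product_stoich),
                "modifiers": list(r.modifiers),
                "rate_law": r.rate_law,
                "reversible": r.reversible,
                "parameters": dict(r.parameters),
            }
            for r in model.reactions
        ],
        "global_parameters": dict(model.global_parameters),
        "annotations": model.annotations,
    }


def _model_from_native(doc: dict) -> NetworkModel:
    if doc.get("format") != NATIVE_FORMAT_TAG:
        raise ModelFormatError(
            f"expected format tag {NATIVE_FORMAT_TAG!r}, got {doc.get('format')!r}"
        )
    try:
        species = [
            SpeciesDef(
                id=s["id"],
                name=s.get("name", s["id"]),
                initial_conc=float(s.get("initial_conc", 0.0)),
                buffered=bool(s.get("buffered", False)),
                compartment=s.get("compartment", "cell"),
            )
            for s in doc["species"]
        ]
        reactions = [
            ReactionDef(
                id=r["id"],
                reactant_stoich={k: int(v) for k, v in r.get("reactants", {}).items()},
                product_stoich={k: int(v) for k, v in r.get("products", {}).items()},
                modifiers=list(r.get("modifiers", [])),
                rate_law=r["rate_law"],
                reversible=bool(r.get("reversible", False)),
                parameters={k: float(v) for k, v in r.get("parameters", {}).items()},
            )
            for r in doc["reactions"]
        ]
    except KeyError as exc:
        raise ModelFormatError(f"missing required field {exc}") from exc
    model = NetworkModel(
        species=species,
        reactions=reactions,
        global_parameters={k: float(v) for k, v in doc.get("global_parameters", {}).items()},
        annotations=doc.get("annotations", {}),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML I/O (libsbml)
# ---------------------------------------------------------------------------

def _sbml_to_model(path: str) -> NetworkModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        loc = f"line {err.getLine()}" if err else "unknown location"
        raise ModelFormatError(f"SBML parse failure at {loc} in {path}")
    sb = doc.getModel()
    if sb is None:
        raise ModelFormatError(f"no <model> element in {path}")

    model = NetworkModel(annotations={"source": str(path), "sbml_name": sb.getName() or sb.getId()})
    compartments: Dict[str, float] = {}
    for i in range(sb.getNumCompartments()):
        c = sb.getCompartment(i)
        size = c.getSize() if c.isSetSize() else 1.0
        compartments[c.getId()] = size if math.isfinite(size) else 1.0

    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        if sp.isSetInitialConcentration():
            conc = sp.getInitialConcentration()
        elif sp.isSetInitialAmount():
            vol = compartments.get(sp.getCompartment(), 1.0)
            conc = sp.getInitialAmount() / vol if vol else sp.getInitialAmount()
        else:
            conc = 0.0
        model.species.append(
            SpeciesDef(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                initial_conc=max(conc, 0.0),
                buffered=bool(sp.getBoundaryCondition() or sp.getConstant()),
                compartment=sp.getCompartment() or "cell",
            )
        )

    for i in range(sb.getNumParameters()):
        p = sb.getParameter(i)
        model.global_parameters[p.getId()] = p.getValue() if p.isSetValue() else 0.0
    # compartment sizes may appear in kinetic laws; expose them as globals
    for cid, size in compartments.items():
        model.global_parameters.setdefault(cid, size)

    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        kl = rx.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise ModelFormatError(
                f"reaction {rx.getId()!r} has no kinetic law; cannot import"
            )
        params: Dict[str, float] = {}
        for k in range(kl.getNumParameters()):
            lp = kl.getParameter(k)
            params[lp.getId()] = lp.getValue()
        for k in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(k)
            params[lp.getId()] = lp.getValue()
        formula = libsbml.formulaToL3String(kl.getMath())
        model.reactions.append(
            ReactionDef(
                id=rx.getId(),
                reactant_stoich={
                    rx.getReactant(k).getSpecies(): int(round(rx.getReactant(k).getStoichiometry() or 1))
                    for k in range(rx.getNumReactants())
                },
                product_stoich={
                    rx.getProduct(k).getSpecies(): int(round(rx.getProduct(k).getStoichiometry() or 1))
                    for k in range(rx.getNumProducts())
                },
                modifiers=[rx.getModifier(k).getSpecies() for k in range(rx.getNumModifiers())],
                rate_law=formula,
                reversible=bool(rx.getReversible()),
                parameters=params,
            )
        )
    model.validate()
    return model


def _model_to_sbml(model: NetworkModel, path: str) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sb = doc.createModel()
    sb.setId(str(model.annotations.get("sbml_name", "model")).replace(" ", "_") or "model")

    comps = sorted({s.compartment for s in model.species}) or ["cell"]
    for cid in comps:
        c = sb.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(float(model.global_parameters.get(cid, 1.0)))
        c.setSpatialDimensions(3)

    for s in model.species:
        sp = sb.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name)
        sp.setCompartment(s.compartment)
        sp.setInitialConcentration(float(s.initial_conc))
        sp.setBoundaryCondition(bool(s.buffered))
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)

    for gname, gval in model.global_parameters.items():
        if gname in comps:
            continue
        p = sb.createParameter()
        p.setId(gname)
        p.setValue(float(gval))
        p.setConstant(True)

    for r in model.reactions:
        rx = sb.createReaction()
        rx.setId(r.id)
        rx.setReversible(bool(r.reversible))
        for sid, n in r.reactant_stoich.items():
            ref = rx.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        for sid, n in r.product_stoich.items():
            ref = rx.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        for sid in r.modifiers:
            ref = rx.createModifier()
            ref.setSpecies(sid)
        kl = rx.createKineticLaw()
        ast = libsbml.parseL3Formula(r.rate_law.replace("**", "^"))
        if ast is None:
            raise ModelFormatError(f"cannot encode rate law of {r.id!r} as SBML math")
        kl.setMath(ast)
        for pname, pval in r.parameters.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(pval))

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise OSError(f"cannot write SBML to {path}")


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    p = str(path).lower()
    return "sbml" if p.endswith((".xml", ".sbml")) else "native"


def load_model(path: str, format: Optional[str] = None) -> NetworkModel:
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        return _sbml_to_model(path)
    if fmt == "native":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelFormatError(
                    f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}"
                ) from exc
        return _model_from_native(doc)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: NetworkModel, path: str, format: Optional[str] = None) -> str:
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _model_to_sbml(model, path)
    elif fmt == "native":
        with open(path, "w") as fh:
            json.dump(_model_to_native(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return str(path)


def models_equivalent(a: NetworkModel, b: NetworkModel, tol: float = 1e-9) -> bool:
    """Semantic equality: species, stoichiometry, rate laws, parameter values."""
    if sorted(a.species_ids()) != sorted(b.species_ids()):
        return False
    for s in a.species:
        t = b.get_species(s.id)
        if s.buffered != t.buffered or abs(s.initial_conc - t.initial_conc) > tol:
            return False
    if sorted(r.id for r in a.reactions) != sorted(r.id for r in b.reactions):
        return False
    for r in a.reactions:
        q = b.get_reaction(r.id)
        if r.reactant_stoich != q.reactant_stoich or r.product_stoich != q.product_stoich:
            return False
        if sorted(r.modifiers) != sorted(q.modifiers):
            return False
        for pname, pval in r.parameters.items():
            if pname not in q.parameters or abs(q.parameters[pname] - pval) > tol * max(1.0, abs(pval)):
                return False
        ea, eb = a.rate_expression(r.id), b.rate_expression(r.id)
        if sympy.simplify(ea - eb) != 0:
            return False
    for g, v in a.global_parameters.items():
        if abs(b.global_parameters.get(g, math.nan) - v) > tol * max(1.0, abs(v)):
            return False
    return True


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def mass_action_reaction(
    rid: str,
    reactants: Mapping[str, int],
    products: Mapping[str, int],
    kf: float,
    kb: Optional[float] = None,
) -> ReactionDef:
    """Build a (reversible) mass-action reaction with law kf*prod(R) - kb*prod(P)."""

    def _term(stoich: Mapping[str, int]) -> str:
        parts = []
        for sid, n in sorted(stoich.items()):
            parts.append(sid if n == 1 else f"{sid}**{n}")
        return "*".join(parts) if parts else "1"

    law = f"kf*{_term(reactants)}"
    params = {"kf": float(kf)}
    reversible = kb is not None
    if reversible:
        law += f" - kb*{_term(products)}"
        params["kb"] = float(kb)
    return ReactionDef(
        id=rid,
        reactant_stoich=dict(reactants),
        product_stoich=dict(products),
        rate_law=law,
        reversible=reversible,
        parameters=params,
    )
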