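"""Quasi-steady-state reduction of Michaelis-Menten motifs and irreversibility tests.

Enzyme sequestration back-propagates signals in mass-action cascades: the
upstream kinase is bound into complexes with its downstream substrates, so the
interaction graph gains edges pointing back up the cascade and the strongly
connected components merge into one large block.  Under QSS conditions
(complex concentrations small) the sequestration disappears, so replacing each

    S + E <-> ES -> P + E

motif by a single irreversible reaction S -> P with the reduced rate

    V = kcat * E * (S/km) / (1 + sum_l S_l/km_l),   km = (k_minus + kcat)/k_plus

(the sum running over all substrates sharing the enzyme E) restores a clean
hierarchy.  These transforms are applied only to a *shadow* model that defines
the hierarchy; simulation and scoring always use the full mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import sympy

from .model import (
    NetworkModel,
    ReactionDef,
    rate_dependencies,
)

__all__ = [
    "MMMotif",
    "EnzymeGroup",
    "find_mm_motifs",
    "qss_reduce",
    "test_forward_irreversibility",
    "apply_irreversibility_for_decomposition",
]


@dataclass
class MMMotif:
    substrate: str
    enzyme: str
    complex: str
    product: str
    k_plus: float
    k_minus: float
    k_cat: float
    binding_reaction: str
    catalysis_reaction: str

    @property
    def km(self) -> float:
        return (self.k_minus + self.k_cat) / self.k_plus


@dataclass
class EnzymeGroup:
    enzyme: str
    motifs: List[MMMotif]


def _mass_action_split(model: NetworkModel, rxn: ReactionDef):
    """Return (kf, kb) rate constants if the law is mass action, else None.

    Matches kf * prod(reactants) [- kb * prod(products)] symbolically.
    """
    expr = model.rate_expression(rxn.id)
    sp = {s.id: sympy.Symbol(s.id) for s in model.species}

    def monomial(stoich):
        m = sympy.Integer(1)
        for sid, n in stoich.items():
            m *= sp[sid] ** n
        return m

    syms = sorted(
        (sp[s] for s in set(rxn.reactant_stoich) | set(rxn.product_stoich)),
        key=str,
    )
    if not syms:
        return None
    try:
        poly = sympy.Poly(sympy.expand(expr), *syms)
    except sympy.PolynomialError:
        return None
    terms = poly.terms()
    kf = kb = sympy.Integer(0)
    fwd_expon = tuple(
        rxn.reactant_stoich.get(str(s), 0) for s in poly.gens
    )
    back_expon = tuple(
        rxn.product_stoich.get(str(s), 0) for s in poly.gens
    )
    for expon, coeff in terms:
        if expon == fwd_expon:
            kf = coeff
        elif expon == back_expon:
            kb = -coeff
        else:
            return None
    return kf, kb


def _numeric(model: NetworkModel, rxn: ReactionDef, expr: sympy.Expr) -> Optional[float]:
    from .model import _local_symbol

    subs = {sympy.Symbol(g): v for g, v in model.global_parameters.items()}
    subs.update({_local_symbol(rxn.id, p): v for p, v in rxn.parameters.items()})
    try:
        val = float(sympy.sympify(expr).evalf(subs=subs))
    except (TypeError, ValueError):
        return None
    return val


def find_mm_motifs(model: NetworkModel) -> List[MMMotif]:
    """Structurally identify S+E <-> ES -> P+E motifs in a mass-action model.

    The complex is identified by its reaction pattern, never by its name: a
    reversible bimolecular binding producing one species, followed by an
    irreversible unimolecular catalysis regenerating the same enzyme.  Motifs
    whose complex also participates in other reactions are skipped.
    """
    motifs: List[MMMotif] = []
    # index reactions touching each species
    touching: Dict[str, List[ReactionDef]] = {}
    for r in model.reactions:
        for sid in set(r.reactant_stoich) | set(r.product_stoich):
            touching.setdefault(sid, []).append(r)

    for bind in model.reactions:
        if not bind.reversible:
            continue
        if sorted(bind.reactant_stoich.values()) != [1, 1] or list(
            bind.product_stoich.values()
        ) != [1]:
            continue
        complex_id = next(iter(bind.product_stoich))
        reactants = sorted(bind.reactant_stoich)
        ma = _mass_action_split(model, bind)
        if ma is None:
            continue
        kf_expr, kb_expr = ma
        for cat in model.reactions:
            if cat.reversible or cat.id == bind.id:
                continue
            if list(cat.reactant_stoich.items()) != [(complex_id, 1)]:
                continue
            prods = sorted(cat.product_stoich)
            if len(cat.product_stoich) != 2 or any(
                v != 1 for v in cat.product_stoich.values()
            ):
                continue
            enzymes = [e for e in reactants if e in prods]
            if len(enzymes) != 1:
                continue
            enzyme = enzymes[0]
            substrate = next(s for s in reactants if s != enzyme)
            product = next(p for p in prods if p != enzyme)
            if product == substrate:
                continue
            cat_ma = _mass_action_split(model, cat)
            if cat_ma is None:
                continue
            # complex must not appear anywhere else
            others = [
                r for r in touching.get(complex_id, [])
                if r.id not in (bind.id, cat.id)
            ]
            if others:
                continue
            k_plus = _numeric(model, bind, kf_expr)
            k_minus = _numeric(model, bind, kb_expr)
            k_cat = _numeric(model, cat, cat_ma[0])
            if None in (k_plus, k_minus, k_cat) or k_plus <= 0 or k_cat <= 0:
                continue
            motifs.append(
                MMMotif(
                    substrate=substrate,
                    enzyme=enzyme,
                    complex=complex_id,
                    product=product,
                    k_plus=k_plus,
                    k_minus=max(k_minus, 0.0),
                    k_cat=k_cat,
                    binding_reaction=bind.id,
                    catalysis_reaction=cat.id,
                )
            )
    return motifs


def group_by_enzyme(motifs: Sequence[MMMotif]) -> List[EnzymeGroup]:
    groups: Dict[str, List[MMMotif]] = {}
    for m in motifs:
        groups.setdefault(m.enzyme, []).append(m)
    return [EnzymeGroup(enzyme=e, motifs=ms) for e, ms in sorted(groups.items())]


def qss_reduce(model: NetworkModel) -> NetworkModel:
    """Replace every MM motif by a reduced reaction; buffer pure enzymes.

    Substrates competing for the same enzyme share the saturation denominator.
    The enzyme and co-substrates are attached as modifiers of the reduced
    reaction.  Species that, in the reduced network, appear only as modifiers
    (never consumed or produced) become buffered.  Eliminated complexes keep a
    record in the model annotations.
    """
    motifs = find_mm_motifs(model)
    if not motifs:
        return model.copy()
    groups = group_by_enzyme(motifs)
    replaced_reactions = {m.binding_reaction for m in motifs} | {
        m.catalysis_reaction for m in motifs
    }
    complexes = {m.complex for m in motifs}

    out = NetworkModel(
        species=[],
        reactions=[r for r in model.copy().reactions if r.id not in replaced_reactions],
        global_parameters=dict(model.global_parameters),
        annotations=dict(model.annotations),
    )
    for s in model.species:
        if s.id in complexes:
            continue
        out.species.append(s)
    out.species = [s.__class__(**{**s.__dict__}) for s in out.species]

    for grp in groups:
        denom_terms = " + ".join(
            f"{m.substrate}/{m.km:.17g}" for m in grp.motifs
        )
        for m in grp.motifs:
            rid = f"qss_{m.substrate}_to_{m.product}"
            law = (
                f"{m.k_cat:.17g} * {m.enzyme} * ({m.substrate}/{m.km:.17g})"
                f" / (1 + {denom_terms})"
            )
            co_substrates = [x.substrate for x in grp.motifs if x is not m]
            out.reactions.append(
                ReactionDef(
                    id=rid,
                    reactant_stoich={m.substrate: 1},
                    product_stoich={m.product: 1},
                    modifiers=[m.enzyme] + co_substrates,
                    rate_law=law,
                    reversible=False,
                    parameters={},
                )
            )

    # exclusively-enzyme species: only ever a modifier in the reduced network
    consumed_or_produced: Set[str] = set()
    for r in out.reactions:
        consumed_or_produced |= set(r.reactant_stoich) | set(r.product_stoich)
    modifier_only = set()
    for s in out.species:
        if s.id in consumed_or_produced or s.buffered:
            continue
        appears = any(
            s.id in rate_dependencies(out, r.id) for r in out.reactions
        )
        if appears:
            s.buffered = True
            modifier_only.add(s.id)

    out.annotations = dict(out.annotations)
    out.annotations["qss_reduction"] = {
        "motifs": [
            {
                "substrate": m.substrate,
                "enzyme": m.enzyme,
                "complex": m.complex,
                "product": m.product,
                "km": m.km,
                "kcat": m.k_cat,
            }
            for m in motifs
        ],
        "buffered_enzymes": sorted(modifier_only),
        "removed_complexes": sorted(complexes),
    }
    out.validate()
    return out


# ---------------------------------------------------------------------------
# forward irreversibility
# ---------------------------------------------------------------------------

def _directional_rates(model: NetworkModel, rid: str):
    """Split a reversible mass-action law into forward/backward sympy exprs."""
    rxn = model.get_reaction(rid)
    ma = _mass_action_split(model, rxn)
    sp = {s.id: sympy.Symbol(s.id) for s in model.species}
    if ma is not None:
        kf, kb = ma
        fwd = kf
        for sid, n in rxn.reactant_stoich.items():
            fwd *= sp[sid] ** n
        back = kb
        for sid, n in rxn.product_stoich.items():
            back *= sp[sid] ** n
        return fwd, back
    # generic split: positive and negative parts of the expanded law
    expr = sympy.expand(model.rate_expression(rid))
    terms = expr.as_ordered_terms()
    fwd = sum(t for t in terms if not str(t).startswith("-")) or sympy.Integer(0)
    back = -(sum(t for t in terms if str(t).startswith("-")) or sympy.Integer(0))
    return fwd, back


def test_forward_irreversibility(
    model: NetworkModel,
    reaction_id: str,
    protocol=None,
    ratio_threshold: float = 0.01,
    t_end: float = 100.0,
    n_samples: int = 200,
    transient_fraction: float = 0.05,
) -> Dict[str, object]:
    """Simulate the full model and compare backward vs forward rates.

    The reaction is *forward irreversible* if R_-(t) <= ratio_threshold *
    R_+(t) at every sampled time after an initial transient window (the first
    ``transient_fraction`` of the simulated span).  ``protocol`` may be an
    :class:`~hoss.scoring.ExperimentDef`; by default the model is run from its
    initial state (settle-then-observe stimulus-free scenario).
    """
    from .model import _local_symbol
    from .simulate import simulate

    rxn = model.get_reaction(reaction_id)
    if not rxn.reversible:
        raise ValueError(f"reaction {reaction_id!r} is not reversible")

    stimuli = []
    if protocol is not None:
        stimuli = list(getattr(protocol, "stimuli", []))
    traj = simulate(model, stimuli=stimuli, clamps=[], t_end=t_end,
                    record_dt=t_end / n_samples)

    fwd_expr, back_expr = _directional_rates(model, reaction_id)
    subs_const = {sympy.Symbol(g): v for g, v in model.global_parameters.items()}
    subs_const.update(
        {_local_symbol(reaction_id, p): v for p, v in rxn.parameters.items()}
    )
    sp_syms = [sympy.Symbol(s.id) for s in model.species]
    f_fwd = sympy.lambdify([sp_syms], fwd_expr.subs(subs_const), "numpy")
    f_back = sympy.lambdify([sp_syms], back_expr.subs(subs_const), "numpy")

    t0 = transient_fraction * traj.times[-1]
    mask = traj.times >= t0
    rplus = np.array([float(f_fwd(x)) for x in traj.concentrations[mask]])
    rminus = np.array([float(f_back(x)) for x in traj.concentrations[mask]])
    if np.all(rplus <= 0):
        return {
            "forward_irreversible": False,
            "max_backward_ratio": float("nan"),
            "inconclusive": True,
        }
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rplus > 0, rminus / rplus, np.inf)
    max_ratio = float(np.max(ratio))
    return {
        "forward_irreversible": bool(max_ratio <= ratio_threshold),
        "max_backward_ratio": max_ratio,
        "inconclusive": False,
    }


def apply_irreversibility_for_decomposition(
    model: NetworkModel, reaction_ids: Sequence[str]
) -> NetworkModel:
    """Shadow model in which listed reversible reactions keep only their forward term.

    Used exclusively to define the hierarchy; the returned model must never be
    simulated in place of the original.
    """
    out = model.copy()
    for rid in reaction_ids:
        rxn = out.get_reaction(rid)
        if not rxn.reversible:
            continue
        fwd, _ = _directional_rates(out, rid)
        # rewrite local symbols back to bare parameter names for serialization
        law = str(fwd)
        for pname in rxn.parameters:
            law = law.replace(f"{rid}__{pname}", pname)
        rxn.rate_law = law
        rxn.reversible = False
    out.annotations = dict(out.annotations)
    out.annotations["decomposition_shadow"] = {
        "forward_irreversible": sorted(set(reaction_ids)),
    }
    return out
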