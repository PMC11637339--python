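"""Synthetic fixture models and experiments.

Two generators make every algorithm in the package testable without external
downloads:

* :func:`generate_synthetic_cascade` builds a mass-action kinase-style cascade
  with a known true parameter set and a known hierarchical decomposition
  (tier 1 depends on nothing, tier 2 only on tier 1, and so on), optionally
  with a feedback edge from the top tier to the bottom one.
* :func:`generate_synthetic_experiments` simulates such a model under simple
  protocols and emits experiment definitions with optional multiplicative
  Gaussian noise.

:func:`huang_ferrell_mapk` reconstructs the classic three-tier MAPK cascade of
coupled phosphorylation/dephosphorylation cycles as elementary mass-action
reactions (a synthetic stand-in built from the published mechanism: 22
species — 8 kinase phospho-forms, 4 enzymes, 10 enzyme-substrate complexes —
and 10 Michaelis-Menten motifs).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    NetworkModel,
    ReactionDef,
    SpeciesDef,
    mass_action_reaction,
)

__all__ = [
    "generate_synthetic_cascade",
    "generate_synthetic_experiments",
    "huang_ferrell_mapk",
]


def generate_synthetic_cascade(
    n_tiers: int = 3,
    species_per_tier: int = 1,
    feedback: Optional[dict] = None,
    seed: int = 0,
) -> Tuple[NetworkModel, Dict[str, float]]:
    """Mass-action activation cascade with known ground-truth parameters.

    Each unit u of tier t is a pair (inactive ``X{t}{u}``, active ``X{t}{u}a``)
    interconverting by an activation reaction (first-order in the inactive
    form, catalysed mass-action-style by one active species of the tier above
    for t > 1) and a first-order deactivation.  Rate constants are drawn
    log-uniformly in [0.5, 2] from ``seed``.  ``feedback`` may be a dict
    ``{"strength": k}``: the deactivation of tier-1 unit 1 is then modulated
    by the top tier's active species, closing a global loop.

    Returns (model, truth) where truth maps parameter paths to true values.
    """
    if n_tiers < 1:
        raise ValueError("n_tiers must be >= 1")
    rng = np.random.default_rng(seed)
    model = NetworkModel(annotations={"fixture": "synthetic_cascade", "seed": seed})
    truth: Dict[str, float] = {}

    def draw() -> float:
        return float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))

    for t in range(1, n_tiers + 1):
        for u in range(1, species_per_tier + 1):
            model.species.append(SpeciesDef(id=f"X{t}{u}", initial_conc=1.0))
            model.species.append(SpeciesDef(id=f"X{t}{u}a", initial_conc=0.0))

    for t in range(1, n_tiers + 1):
        for u in range(1, species_per_tier + 1):
            kact, kdeact = draw(), draw()
            act_id, deact_id = f"act_{t}_{u}", f"deact_{t}_{u}"
            if t == 1:
                law = f"kact*X{t}{u}"
            else:
                up = (u - 1) % species_per_tier + 1
                law = f"kact*X{t}{u}*X{t-1}{up}a"
            model.reactions.append(
                ReactionDef(
                    id=act_id,
                    reactant_stoich={f"X{t}{u}": 1},
                    product_stoich={f"X{t}{u}a": 1},
                    rate_law=law,
                    parameters={"kact": kact},
                )
            )
            deact_law = f"kdeact*X{t}{u}a"
            params = {"kdeact": kdeact}
            if feedback and t == 1 and u == 1 and n_tiers > 1:
                kfb = float(feedback.get("strength", 1.0))
                deact_law = f"kdeact*X{t}{u}a*(1 + kfb*X{n_tiers}1a)"
                params["kfb"] = kfb
                truth[f"{deact_id}.kfb"] = kfb
            model.reactions.append(
                ReactionDef(
                    id=deact_id,
                    reactant_stoich={f"X{t}{u}a": 1},
                    product_stoich={f"X{t}{u}": 1},
                    rate_law=deact_law,
                    parameters=params,
                )
            )
            truth[f"{act_id}.kact"] = kact
            truth[f"{deact_id}.kdeact"] = kdeact

    model.validate()
    return model, truth


def generate_synthetic_experiments(
    model: NetworkModel,
    truth_params: Optional[Dict[str, float]] = None,
    templates: Optional[Sequence[dict]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> List["ExperimentDef"]:
    """Simulate the truth model and sample noisy experiment definitions.

    Templates are dicts: ``{"protocol": "timeseries", "readouts": [ids],
    "times": [...], "stimuli": [...], "weight": w}`` (dose_response and
    bar_chart variants analogous, with "doses"/"conditions").  The default is
    one time-series per readout-bearing species ending in "a" (active forms),
    sampled on a 12-point grid from the cold start, which exposes both the
    relaxation rate and the steady-state level of every cascade unit.

    Noise is multiplicative Gaussian: y = x * (1 + noise_sd * eps).  With
    noise_sd=0 the data reproduce the truth exactly.
    """
    from .model import ParameterRef, set_parameter_inplace
    from .scoring import ExperimentDef, ReadoutSeries
    from .simulate import StimulusEvent, run_protocol

    truth = model.copy()
    for path, val in (truth_params or {}).items():
        set_parameter_inplace(truth, ParameterRef(path), val)

    if templates is None:
        active = [s.id for s in model.species if s.id.endswith("a") and not s.buffered]
        times = list(np.linspace(0.25, 8.0, 12))
        templates = [
            {"protocol": "timeseries", "readouts": [sid], "times": times, "weight": 1.0}
            for sid in active
        ]

    rng = np.random.default_rng(seed)
    out: List[ExperimentDef] = []
    for k, tpl in enumerate(templates):
        proto = tpl.get("protocol", "timeseries")
        stimuli = [
            StimulusEvent(**e) if isinstance(e, dict) else e
            for e in tpl.get("stimuli", [])
        ]
        readout_ids = tpl["readouts"]
        if proto == "timeseries":
            xs = [float(t) for t in tpl["times"]]
        elif proto == "dose_response":
            xs = [float(d) for d in tpl["doses"]["values"]]
        elif proto == "bar_chart":
            xs = [float(i) for i in range(len(tpl["conditions"]))]
        else:
            raise ValueError(f"cannot synthesize protocol {proto!r}")
        probe = ExperimentDef(
            id=f"synth_{k}_{proto}",
            protocol=proto,
            readouts=[
                ReadoutSeries(entity=sid, points=[[x, 1.0] for x in xs])
                for sid in readout_ids
            ],
            stimuli=stimuli,
            doses=tpl.get("doses"),
            conditions=tpl.get("conditions"),
            settle_time=tpl.get("settle_time", 0.0),
            weight=float(tpl.get("weight", 1.0)),
            metadata={"synthetic": True, "noise_sd": noise_sd, "seed": seed},
        )
        preds = run_protocol(truth, probe)
        for ro in probe.readouts:
            y = np.asarray(preds[ro.entity], dtype=float)
            if noise_sd > 0:
                y = y * (1.0 + noise_sd * rng.standard_normal(y.shape))
            ro.points = [[x, float(val)] for x, val in zip(ro.x(), y)]
        out.append(probe)
    return out


# ---------------------------------------------------------------------------
# the classic three-tier MAPK cascade (mass-action reconstruction)
# ---------------------------------------------------------------------------

def huang_ferrell_mapk() -> NetworkModel:
    """Mass-action three-tier MAPK cascade (synthetic reconstruction).

    22 species and 10 enzymatic cycles built as elementary S+E <-> ES -> P+E
    steps: the top kinase (KKK) is activated by enzyme E1 and deactivated by
    E2; the middle kinase (KK) is doubly phosphorylated by active KKK and
    dephosphorylated by KKPase; MAPK (K) is doubly phosphorylated by KK_PP and
    dephosphorylated by KPase.  Representative constants: association
    1000 /(uM s), dissociation 150 /s, catalysis 150 /s; totals 3e-3 uM (KKK),
    1.2 uM (KK, K), 3e-5/3e-4/3e-4/0.12 uM for E1/E2/KKPase/KPase.
    """
    m = NetworkModel(annotations={"fixture": "mapk_cascade_mass_action"})
    concs = {
        "KKK": 3e-3, "KKK_st": 0.0,
        "KK": 1.2, "KK_P": 0.0, "KK_PP": 0.0,
        "K": 1.2, "K_P": 0.0, "K_PP": 0.0,
        "E1": 3e-5, "E2": 3e-4, "KKPase": 3e-4, "KPase": 0.12,
    }
    motifs = [
        ("KKK", "E1", "KKK_st"),
        ("KKK_st", "E2", "KKK"),
        ("KK", "KKK_st", "KK_P"),
        ("KK_P", "KKK_st", "KK_PP"),
        ("KK_P", "KKPase", "KK"),
        ("KK_PP", "KKPase", "KK_P"),
        ("K", "KK_PP", "K_P"),
        ("K_P", "KK_PP", "K_PP"),
        ("K_P", "KPase", "K"),
        ("K_PP", "KPase", "K_P"),
    ]
    for sid, c in concs.items():
        m.species.append(SpeciesDef(id=sid, initial_conc=c))
    a, d, k = 1000.0, 150.0, 150.0
    for n, (sub, enz, prod) in enumerate(motifs, start=1):
        cplx = f"C{n}_{sub}_{enz}"
        m.species.append(SpeciesDef(id=cplx, initial_conc=0.0))
        m.reactions.append(
            mass_action_reaction(f"bind{n}", {sub: 1, enz: 1}, {cplx: 1}, kf=a, kb=d)
        )
        m.reactions.append(
            mass_action_reaction(f"cat{n}", {cplx: 1}, {prod: 1, enz: 1}, kf=k)
        )
    m.validate()
    return m
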