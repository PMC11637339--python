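"""Experiment definitions, NRMS/WNRMS cost functions, and model scoring.

Experiments are stored in the ``hoss-exp-1`` JSON dialect: a stimulus protocol
(time-series, dose-response, bar-chart, or direct parameter estimate), one or
more readout series with data points, and a positive weight.  The default
objective is the normalized root-mean-square cost

    NRMS(theta) = sqrt( (1/N_d) sum_{i,k} ((y_ik - x_i(t_k, theta)) / m_i)^2 )

where m_i is the maximum observation of readout i within the experiment and
N_d counts all data points, combined across experiments by the weighted
quadratic mean

    WNRMS(theta) = sqrt( sum_j w_j NRMS_j^2 / sum_j w_j ).

A Gaussian negative log-likelihood with per-readout scaling s_i and standard
deviation sigma_i is available as an alternative objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import NetworkModel
from .simulate import ClampSpec, StimulusEvent, run_protocol

__all__ = [
    "ReadoutSeries",
    "ExperimentDef",
    "CostReport",
    "read_experiment",
    "write_experiment",
    "nrms",
    "wnrms",
    "neg_log_likelihood",
    "score_model",
]

EXP_FORMAT_TAG = "hoss-exp-1"
PROTOCOLS = ("timeseries", "dose_response", "bar_chart", "direct_parameter")


class ExperimentFormatError(ValueError):
    pass


@dataclass
class ReadoutSeries:
    entity: str
    points: List[List[float]]  # [x, y] or [x, y, sd]
    normalization: str = "max"  # "max" | "none"

    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    def norm_constant(self) -> float:
        if self.normalization == "none":
            return 1.0
        m = float(np.max(np.abs(self.y()))) if self.points else 0.0
        if m == 0.0:
            raise ExperimentFormatError(
                f"readout {self.entity!r}: all observations zero, max-normalization undefined"
            )
        return m


@dataclass
class ExperimentDef:
    id: str
    protocol: str
    readouts: List[ReadoutSeries]
    stimuli: List[StimulusEvent] = field(default_factory=list)
    doses: Optional[Dict[str, object]] = None
    conditions: Optional[List[Dict[str, float]]] = None
    settle_time: Optional[float] = None
    weight: float = 1.0
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ExperimentFormatError(f"unknown protocol {self.protocol!r}")
        if self.weight <= 0:
            raise ExperimentFormatError("weight must be > 0")
        if not self.readouts or any(not ro.points for ro in self.readouts):
            raise ExperimentFormatError("need >= 1 readout with >= 1 data point")

    def n_points(self) -> int:
        return sum(len(ro.points) for ro in self.readouts)


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def _exp_to_dict(exp: ExperimentDef) -> dict:
    doc = {
        "format": EXP_FORMAT_TAG,
        "id": exp.id,
        "protocol": exp.protocol,
        "weight": exp.weight,
        "readouts": [
            {
                "entity": ro.entity,
                "points": [[float(v) for v in p] for p in ro.points],
                "normalization": ro.normalization,
            }
            for ro in exp.readouts
        ],
        "metadata": exp.metadata,
    }
    if exp.settle_time is not None:
        doc["settle_time"] = exp.settle_time
    if exp.stimuli:
        doc["stimuli"] = [
            {"entity": e.entity, "time": e.time, "value": e.value, "mode": e.mode}
            for e in exp.stimuli
        ]
    if exp.doses is not None:
        doc["doses"] = exp.doses
    if exp.conditions is not None:
        doc["conditions"] = exp.conditions
    return doc


def _exp_from_dict(doc: dict) -> ExperimentDef:
    from .schemas import validate_experiment

    validate_experiment(doc)
    return ExperimentDef(
        id=doc["id"],
        protocol=doc["protocol"],
        readouts=[
            ReadoutSeries(
                entity=ro["entity"],
                points=[list(map(float, p)) for p in ro["points"]],
                normalization=ro.get("normalization", "max"),
            )
            for ro in doc["readouts"]
        ],
        stimuli=[
            StimulusEvent(
                entity=e["entity"], time=float(e["time"]), value=float(e["value"]),
                mode=e.get("mode", "set_buffered"),
            )
            for e in doc.get("stimuli", [])
        ],
        doses=doc.get("doses"),
        conditions=doc.get("conditions"),
        settle_time=doc.get("settle_time"),
        weight=float(doc.get("weight", 1.0)),
        metadata=doc.get("metadata", {}),
    )


def read_experiment(path: str) -> ExperimentDef:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ExperimentFormatError(f"{path}: invalid JSON: {exc}") from exc
    return _exp_from_dict(doc)


def write_experiment(exp: ExperimentDef, path: str) -> str:
    with open(path, "w") as fh:
        json.dump(_exp_to_dict(exp), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return str(path)


# ---------------------------------------------------------------------------
# cost functions
# ---------------------------------------------------------------------------

def nrms(
    predictions: Mapping[str, np.ndarray],
    observations: Sequence[ReadoutSeries],
    self_normalized: bool = False,
) -> float:
    """Normalized root-mean-square cost over all points of one experiment.

    ``self_normalized`` divides each residual by its own observation instead
    of the readout maximum (used for direct parameter estimates).
    """
    sq = 0.0
    n = 0
    for ro in observations:
        if ro.entity not in predictions:
            raise KeyError(f"missing prediction for readout {ro.entity!r}")
        pred = np.asarray(predictions[ro.entity], dtype=float)
        y = ro.y()
        if pred.shape != y.shape:
            raise ValueError(
                f"readout {ro.entity!r}: {len(pred)} predictions for {len(y)} points"
            )
        if self_normalized:
            if np.any(y == 0):
                raise ExperimentFormatError(
                    f"readout {ro.entity!r}: zero target in direct parameter estimate"
                )
            sq += float(np.sum(((y - pred) / y) ** 2))
        else:
            m = ro.norm_constant()
            sq += float(np.sum(((y - pred) / m) ** 2))
        n += len(y)
    if n == 0:
        raise ValueError("no data points")
    return math.sqrt(sq / n)


def wnrms(nrms_values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted quadratic mean of per-experiment NRMS values."""
    if len(nrms_values) != len(weights):
        raise ValueError("nrms_values and weights must have equal length")
    if len(nrms_values) == 0:
        raise ValueError("empty cost list")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    v = np.asarray(nrms_values, dtype=float)
    return math.sqrt(float(np.sum(w * v**2) / np.sum(w)))


def neg_log_likelihood(
    predictions: Sequence[float],
    observations: Sequence[float],
    s: Sequence[float],
    sigma: Sequence[float],
) -> float:
    """Gaussian negative log-likelihood with scaling s_i and noise sigma_i.

    L = 1/2 sum_i [ log(2 pi sigma_i^2) + ((y_i - s_i x_i)/sigma_i)^2 ]
    """
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    sv = np.broadcast_to(np.asarray(s, dtype=float), y.shape)
    sg = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape)
    if np.any(sg <= 0):
        raise ValueError("sigma must be positive")
    return float(0.5 * np.sum(np.log(2 * np.pi * sg**2) + ((y - sv * x) / sg) ** 2))


# ---------------------------------------------------------------------------
# model scoring
# ---------------------------------------------------------------------------

@dataclass
class CostReport:
    entries: List[dict]
    wnrms: float
    n_scored: int
    n_skipped: int

    def to_json(self) -> dict:
        return {
            "wnrms": self.wnrms,
            "n_scored": self.n_scored,
            "n_skipped": self.n_skipped,
            "experiments": self.entries,
        }

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.entries).to_csv(path, index=False, float_format="%.12g")


def score_model(
    model: NetworkModel,
    experiments: Sequence[ExperimentDef],
    clamps: Sequence[ClampSpec] = (),
    weights: Optional[Sequence[float]] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> CostReport:
    """Run every experiment protocol on the model and combine costs by WNRMS.

    Experiments whose entities do not exist in the model are skipped with a
    report entry (entity mismatch); scoring fails only if nothing applies.
    ``weights`` overrides the experiments' stored weights (pipeline configs
    take precedence over experiment files).
    """
    entries: List[dict] = []
    costs: List[float] = []
    used_weights: List[float] = []
    for k, exp in enumerate(experiments):
        w = float(weights[k]) if weights is not None else exp.weight
        try:
            preds = run_protocol(model, exp, clamps=clamps, rtol=rtol, atol=atol)
            c = nrms(preds, exp.readouts,
                     self_normalized=exp.protocol == "direct_parameter")
        except KeyError as exc:
            entries.append(
                {"experiment": exp.id, "nrms": math.nan, "n_points": exp.n_points(),
                 "weight": w, "skipped": True, "reason": str(exc)}
            )
            continue
        entries.append(
            {"experiment": exp.id, "nrms": c, "n_points": exp.n_points(),
             "weight": w, "skipped": False, "reason": ""}
        )
        costs.append(c)
        used_weights.append(w)
    if not costs:
        raise ValueError("all experiments were skipped (entity mismatch)")
    return CostReport(
        entries=entries,
        wnrms=wnrms(costs, used_weights),
        n_scored=len(costs),
        n_skipped=len(entries) - len(costs),
    )


# re-exported synthetic-fixture generators (part of the scoring surface)
from .synth import generate_synthetic_cascade, generate_synthetic_experiments  # noqa: E402,F401
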