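"""Stiff ODE simulation of network models under experimental protocols.

The semiflow integrates dx/dt = S . R(x, p) for non-buffered species with a
stiff-capable solver (LSODA, rtol 1e-6 / atol 1e-9 by default).  Stimulus
events restart the integration at their event times; *clamped* species are
pinned to the linear interpolation of a data time series (the "dependent
input" device that lets a feedback block be optimized in isolation), and
buffered species stay constant.

Rate laws are compiled once per model *structure* (sympy lambdify over the
species and parameter vectors) and cached, so repeated scoring during
optimization only re-binds parameter values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from .model import (
    NetworkModel,
    ParameterRef,
    get_parameter,
    stoichiometric_matrix,
    _local_symbol,
)

__all__ = [
    "StimulusEvent",
    "ClampSpec",
    "Trajectory",
    "SimulationError",
    "simulate",
    "settle",
    "run_protocol",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


class SimulationError(RuntimeError):
    pass


@dataclass
class StimulusEvent:
    entity: str
    time: float
    value: float
    mode: str = "set_buffered"  # or "set_concentration"


@dataclass
class ClampSpec:
    entity: str
    time_series: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.time_series) < 2:
            raise ValueError("clamp needs at least 2 points")
        ts = [t for t, _ in self.time_series]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("clamp times must be strictly increasing")

    def value_at(self, t: float) -> float:
        ts = np.array([p[0] for p in self.time_series])
        vs = np.array([p[1] for p in self.time_series])
        return float(np.interp(t, ts, vs))  # np.interp holds endpoints


@dataclass
class Trajectory:
    times: np.ndarray
    concentrations: np.ndarray  # (#times, #species)
    species_ids: List[str]

    def column(self, sid: str) -> np.ndarray:
        return self.concentrations[:, self.species_ids.index(sid)]

    def to_csv(self, path: str) -> None:
        import pandas as pd

        df = pd.DataFrame(self.concentrations, columns=self.species_ids)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# compiled ODE right-hand sides, cached per model structure
# ---------------------------------------------------------------------------

_COMPILED_CACHE: Dict[tuple, "CompiledODE"] = {}


class CompiledODE:
    def __init__(self, model: NetworkModel):
        self.species_ids = model.species_ids()
        self.param_names: List[str] = []
        exprs = []
        for r in model.reactions:
            exprs.append(model.rate_expression(r.id))
            for p in r.parameters:
                self.param_names.append(f"{r.id}__{p}")
        for g in model.global_parameters:
            self.param_names.append(g)
        x_syms = [sympy.Symbol(s) for s in self.species_ids]
        p_syms = [sympy.Symbol(p) for p in self.param_names]
        self._rates = sympy.lambdify([x_syms, p_syms], exprs, "numpy")
        self.S = stoichiometric_matrix(model).astype(float)

    def param_values(self, model: NetworkModel) -> np.ndarray:
        vals = []
        for name in self.param_names:
            if "__" in name:
                rid, pname = name.split("__", 1)
                vals.append(model.get_reaction(rid).parameters[pname])
            else:
                vals.append(model.global_parameters[name])
        return np.asarray(vals, dtype=float)

    def rates(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.asarray(self._rates(x, p), dtype=float)


def _structure_key(model: NetworkModel) -> tuple:
    return (
        tuple(model.species_ids()),
        tuple((r.id, r.rate_law, tuple(sorted(r.parameters))) for r in model.reactions),
        tuple(sorted(model.global_parameters)),
    )


def compiled_ode(model: NetworkModel) -> CompiledODE:
    key = _structure_key(model)
    ode = _COMPILED_CACHE.get(key)
    if ode is None:
        ode = CompiledODE(model)
        if len(_COMPILED_CACHE) > 64:
            _COMPILED_CACHE.clear()
        _COMPILED_CACHE[key] = ode
    return ode


# ---------------------------------------------------------------------------
# core integration
# ---------------------------------------------------------------------------

def _integrate_segment(
    ode: CompiledODE,
    x0: np.ndarray,
    p: np.ndarray,
    frozen: np.ndarray,
    clamp_idx: List[int],
    clamp_fns: List,
    t_span: Tuple[float, float],
    t_eval: Optional[np.ndarray],
    rtol: float,
    atol: float,
):
    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xe = np.maximum(x, 0.0)
        for i, fn in zip(clamp_idx, clamp_fns):
            xe[i] = fn(t)
        dx = ode.S @ ode.rates(xe, p)
        dx[frozen] = 0.0
        return dx

    sol = solve_ivp(
        rhs,
        t_span,
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integrator failed in [{t_span[0]}, {t_span[1]}]: {sol.message}; "
            f"state={x0.tolist()}"
        )
    return sol


def simulate(
    model: NetworkModel,
    stimuli: Sequence[StimulusEvent] = (),
    clamps: Sequence[ClampSpec] = (),
    t_end: float = 100.0,
    record_dt: Optional[float] = None,
    record_times: Optional[Sequence[float]] = None,
    x0: Optional[np.ndarray] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model under a stimulus protocol and optional clamps.

    Events with time <= 0 are applied to the initial state.  Recording is at
    ``record_times`` if given, else on a uniform grid of step ``record_dt``
    (default t_end/100).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    ode = compiled_ode(model)
    idx = {s: i for i, s in enumerate(ode.species_ids)}
    p = ode.param_values(model)

    x = np.array([s.initial_conc for s in model.species], dtype=float) if x0 is None \
        else np.asarray(x0, dtype=float).copy()
    buffered = np.array([s.buffered for s in model.species], dtype=bool)

    clamp_idx = [idx[c.entity] for c in clamps]
    clamp_fns = [c.value_at for c in clamps]
    frozen = buffered.copy()
    for i in clamp_idx:
        frozen[i] = True

    if record_times is not None:
        rec = np.asarray(sorted(set(float(t) for t in record_times)))
    else:
        dt = record_dt if record_dt else t_end / 100.0
        rec = np.arange(0.0, t_end + dt / 2, dt)
    rec = rec[(rec >= 0) & (rec <= t_end)]

    events = sorted(stimuli, key=lambda e: e.time)
    for e in events:
        if e.time <= 0:
            x[idx[e.entity]] = e.value
            if e.mode == "set_buffered":
                frozen[idx[e.entity]] = True
    boundaries = sorted({e.time for e in events if 0 < e.time < t_end}) + [t_end]

    times_out: List[float] = []
    states_out: List[np.ndarray] = []
    if rec.size and rec[0] == 0.0:
        times_out.append(0.0)
        x_rec = x.copy()
        for i, fn in zip(clamp_idx, clamp_fns):
            x_rec[i] = fn(0.0)
        states_out.append(x_rec)

    t_prev = 0.0
    for t_next in boundaries:
        seg_rec = rec[(rec > t_prev) & (rec <= t_next)]
        seg_eval = np.append(seg_rec, t_next) if (
            seg_rec.size == 0 or seg_rec[-1] < t_next
        ) else seg_rec
        sol = _integrate_segment(
            ode, x, p, frozen, clamp_idx, clamp_fns,
            (t_prev, t_next), seg_eval, rtol, atol,
        )
        for k, t in enumerate(sol.t[: len(seg_rec)]):
            xs = sol.y[:, k].copy()
            for i, fn in zip(clamp_idx, clamp_fns):
                xs[i] = fn(t)
            times_out.append(float(t))
            states_out.append(xs)
        x = np.asarray(sol.y[:, -1], dtype=float).copy()
        for e in events:
            if e.time == t_next or (t_prev < e.time <= t_next and e.time != t_prev):
                if abs(e.time - t_next) < 1e-12:
                    x[idx[e.entity]] = e.value
                    if e.mode == "set_buffered":
                        frozen[idx[e.entity]] = True
        t_prev = t_next

    conc = np.asarray(states_out)
    if conc.size == 0:
        raise SimulationError("no recording points inside the simulated span")
    neg = conc.min()
    if neg < -max(atol * 100, 1e-7) * max(1.0, abs(conc).max()):
        raise SimulationError(f"negative concentration beyond tolerance: {neg}")
    conc = np.clip(conc, 0.0, None)
    return Trajectory(
        times=np.asarray(times_out), concentrations=conc, species_ids=list(ode.species_ids)
    )


def settle(
    model: NetworkModel,
    stimuli_baseline: Sequence[StimulusEvent] = (),
    tol: float = 1e-6,
    t_max: float = 1e6,
    x0: Optional[np.ndarray] = None,
    settle_time: Optional[float] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Tuple[np.ndarray, bool]:
    """Integrate to steady state; returns (state, converged).

    Convergence: ||dx/dt||_inf < tol * max(1, ||x||_inf) on the free species.
    With ``settle_time`` set, a fixed-duration settle is performed instead and
    the criterion is evaluated once at the end.  A model that keeps moving
    (e.g. a limit cycle) returns converged=False with the state at t_max.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ode = compiled_ode(model)
    idx = {s: i for i, s in enumerate(ode.species_ids)}
    p = ode.param_values(model)
    x = np.array([s.initial_conc for s in model.species], dtype=float) if x0 is None \
        else np.asarray(x0, dtype=float).copy()
    frozen = np.array([s.buffered for s in model.species], dtype=bool)
    for e in stimuli_baseline:
        x[idx[e.entity]] = e.value
        if e.mode == "set_buffered":
            frozen[idx[e.entity]] = True

    def deriv_ok(xv: np.ndarray) -> bool:
        dx = ode.S @ ode.rates(np.maximum(xv, 0.0), p)
        dx[frozen] = 0.0
        return float(np.max(np.abs(dx))) < tol * max(1.0, float(np.max(np.abs(xv))))

    if t_max <= 0 or (settle_time is not None and settle_time <= 0):
        return x, deriv_ok(x) if t_max > 0 else False
    if deriv_ok(x):
        return x, True

    if settle_time is not None:
        sol = _integrate_segment(ode, x, p, frozen, [], [], (0.0, settle_time), None,
                                 rtol, atol)
        xf = np.maximum(np.asarray(sol.y[:, -1], dtype=float), 0.0)
        return xf, deriv_ok(xf)

    t = min(1.0, t_max)
    while True:
        sol = _integrate_segment(ode, x, p, frozen, [], [], (0.0, t), None, rtol, atol)
        x = np.maximum(np.asarray(sol.y[:, -1], dtype=float), 0.0)
        if deriv_ok(x):
            return x, True
        if t >= t_max:
            return x, False
        t = min(t * 10.0, t_max)


# ---------------------------------------------------------------------------
# experimental protocols
# ---------------------------------------------------------------------------

def run_protocol(
    model: NetworkModel,
    experiment,
    clamps: Sequence[ClampSpec] = (),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Dict[str, np.ndarray]:
    """Predicted readout values for every data point of an experiment.

    Returns a map readout-entity -> array aligned with the readout's points.
    Unknown entities raise KeyError; the caller decides whether to skip the
    experiment (see :func:`hoss.scoring.score_model`).
    """
    known = set(model.species_ids())
    proto = experiment.protocol

    if proto == "direct_parameter":
        out = {}
        for ro in experiment.readouts:
            val = get_parameter(model, ParameterRef(ro.entity))
            out[ro.entity] = np.full(len(ro.points), val)
        return out

    for ro in experiment.readouts:
        if ro.entity not in known:
            raise KeyError(f"readout entity {ro.entity!r} not in model")

    if proto == "timeseries":
        x_settled, _ = settle(
            model,
            [e for e in experiment.stimuli if e.time <= 0],
            settle_time=experiment.settle_time,
            rtol=rtol, atol=atol,
        )
        data_times = sorted({float(pt[0]) for ro in experiment.readouts for pt in ro.points})
        t_end = max(data_times) if data_times and max(data_times) > 0 else 1.0
        traj = simulate(
            model,
            stimuli=[e for e in experiment.stimuli if e.time > 0],
            clamps=clamps,
            t_end=t_end,
            record_times=data_times or None,
            x0=x_settled,
            rtol=rtol, atol=atol,
        )
        out = {}
        for ro in experiment.readouts:
            ts = np.array([float(pt[0]) for pt in ro.points])
            out[ro.entity] = np.interp(ts, traj.times, traj.column(ro.entity))
        return out

    if proto == "dose_response":
        entity = experiment.doses["entity"]
        if entity not in known:
            raise KeyError(f"dose entity {entity!r} not in model")
        values = [float(v) for v in experiment.doses["values"]]
        i_ent = model.species_index()[entity]
        steady: Dict[float, np.ndarray] = {}
        for dose in values:
            ev = [StimulusEvent(entity=entity, time=0.0, value=dose, mode="set_buffered")]
            xs, _ = settle(model, ev, settle_time=experiment.settle_time,
                           rtol=rtol, atol=atol)
            steady[dose] = xs
        sidx = model.species_index()
        out = {}
        for ro in experiment.readouts:
            preds = []
            for pt in ro.points:
                dose = float(pt[0])
                if dose not in steady:
                    ev = [StimulusEvent(entity=entity, time=0.0, value=dose,
                                        mode="set_buffered")]
                    steady[dose], _ = settle(model, ev,
                                             settle_time=experiment.settle_time,
                                             rtol=rtol, atol=atol)
                preds.append(steady[dose][sidx[ro.entity]])
            out[ro.entity] = np.asarray(preds)
        return out

    if proto == "bar_chart":
        sidx = model.species_index()
        states = []
        for cond in experiment.conditions:
            ev = [
                StimulusEvent(entity=ent, time=0.0, value=float(val), mode="set_buffered")
                for ent, val in sorted(cond.items())
            ]
            for e in ev:
                if e.entity not in known:
                    raise KeyError(f"condition entity {e.entity!r} not in model")
            xs, _ = settle(model, ev, settle_time=experiment.settle_time,
                           rtol=rtol, atol=atol)
            states.append(xs)
        out = {}
        for ro in experiment.readouts:
            preds = []
            for pt in ro.points:
                k = int(round(float(pt[0])))
                if not 0 <= k < len(states):
                    raise KeyError(f"bar-chart condition index {k} out of range")
                preds.append(states[k][sidx[ro.entity]])
            out[ro.entity] = np.asarray(preds)
        return out

    raise ValueError(f"unknown protocol {proto!r}")
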