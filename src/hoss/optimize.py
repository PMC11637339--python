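"""Optimization methods: flat, nested hierarchical, multistart, and staged Monte Carlo.

Four methods minimize the weighted NRMS cost over a parameter space:

* ``flat``          — one joint minimization over all parameters (the baseline).
* ``hierarchical``  — level-by-level minimization along a nested decomposition:
  each block is fitted against its own experiments while everything upstream
  is frozen at its already-optimized values.
* ``initScram``     — multistart: a population of starting models with
  parameters scrambled log-uniformly around the nominal values, each optimized
  hierarchically; optionally repeated rounds re-scramble around the incumbent.
* ``hossMC``        — staged Monte Carlo: at every hierarchy level each of N
  carried parent models spawns scrambled variants per block, blocks are
  optimized independently, rank-paired within each parent, and the best N
  merged models are carried to the next level.

Parameter scrambling follows p = p_nom * exp(log a + log(b/a) * U) with
b = 1/a = scram_range and U uniform on [0, 1] (log-uniform in [p/r, p*r]) or
standard normal (log-normal).  Optimization operates in log-parameter space by
default, with COBYLA as the default algorithm.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize as sciopt

from .decompose import Decomposition, build_interaction_graph
from .model import (
    NetworkModel,
    ParameterRef,
    get_parameter,
    set_parameter_inplace,
)
from .scoring import ExperimentDef, score_model
from .simulate import ClampSpec

__all__ = [
    "ParamSpace",
    "ScrambleSpec",
    "BlockSpec",
    "OptResult",
    "scramble",
    "scramble_with_u",
    "optimize_flat",
    "optimize_hierarchical",
    "block_specs_from_decomposition",
    "make_dependent_input_clamps",
    "init_scram",
    "hoss_mc",
    "compare_parameter_sets",
    "derive_seed",
]

_ALGORITHMS = {
    "COBYLA": "COBYLA",
    "SLSQP": "SLSQP",
    "BFGS": "BFGS",
    "NelderMead": "Nelder-Mead",
}
DEFAULT_BOUND_FOLD = 1000.0


def derive_seed(master_seed: int, *task_path: int) -> int:
    """Deterministic counter-based seed for a task, independent of scheduling."""
    ss = np.random.SeedSequence([int(master_seed)] + [int(t) for t in task_path])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# parameter space
# ---------------------------------------------------------------------------

@dataclass
class ParamSpace:
    refs: List[ParameterRef]
    bounds: List[Tuple[float, float]]
    scale: str = "log"  # "log" | "linear"

    def __post_init__(self) -> None:
        if len(self.refs) != len(self.bounds):
            raise ValueError("refs and bounds length mismatch")
        for ref, (lo, hi) in zip(self.refs, self.bounds):
            if not (0 < lo < hi) and self.scale == "log":
                raise ValueError(f"{ref.path}: log-scale bounds must satisfy 0 < lo < hi")
            if lo >= hi:
                raise ValueError(f"{ref.path}: lower bound must be < upper bound")

    @classmethod
    def from_paths(
        cls,
        model: NetworkModel,
        paths: Sequence[str],
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        scale: str = "log",
        default_fold: float = DEFAULT_BOUND_FOLD,
    ) -> "ParamSpace":
        refs = [ParameterRef(p) for p in paths]
        out_bounds = []
        for ref in refs:
            if bounds and ref.path in bounds:
                lo, hi = bounds[ref.path]
            else:
                nominal = get_parameter(model, ref)
                if nominal <= 0:
                    nominal = 1e-6
                lo, hi = nominal / default_fold, nominal * default_fold
            out_bounds.append((float(lo), float(hi)))
        return cls(refs=refs, bounds=out_bounds, scale=scale)

    def values(self, model: NetworkModel) -> np.ndarray:
        return np.array([get_parameter(model, r) for r in self.refs])

    def apply(self, model: NetworkModel, values: Sequence[float]) -> None:
        for ref, v in zip(self.refs, values):
            set_parameter_inplace(model, ref, float(v))

    # optimizer-space transform
    def to_theta(self, values: np.ndarray) -> np.ndarray:
        return np.log(values) if self.scale == "log" else np.asarray(values, float)

    def from_theta(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(theta) if self.scale == "log" else np.asarray(theta, float)

    def theta_bounds(self) -> List[Tuple[float, float]]:
        if self.scale == "log":
            return [(math.log(lo), math.log(hi)) for lo, hi in self.bounds]
        return list(self.bounds)


# ---------------------------------------------------------------------------
# scrambling
# ---------------------------------------------------------------------------

@dataclass
class ScrambleSpec:
    scram_range: float = 2.0
    distribution: str = "uniform"  # "uniform" | "normal"
    count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scram_range <= 1:
            raise ValueError("scram_range must be > 1")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def scramble_with_u(
    nominal: np.ndarray, scram_range: float, u: np.ndarray
) -> np.ndarray:
    """p = nominal * exp(log a + log(b/a) * U) with b = 1/a = scram_range."""
    nominal = np.asarray(nominal, dtype=float)
    if np.any(nominal <= 0):
        raise ValueError("nominal parameters must be positive for log scrambling")
    a = 1.0 / scram_range
    b = scram_range
    return nominal * np.exp(math.log(a) + math.log(b / a) * np.asarray(u, float))


def scramble(nominal: Sequence[float], spec: ScrambleSpec) -> List[np.ndarray]:
    """Generate spec.count scrambled parameter vectors (deterministic in seed)."""
    nominal = np.asarray(nominal, dtype=float)
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.count):
        if spec.distribution == "uniform":
            u = rng.uniform(0.0, 1.0, nominal.shape)
        else:
            # centred log-normal: U ~ N(0,1) maps through the same formula's
            # half-width, i.e. log(p/nominal) = log(b) * U
            u = 0.5 + 0.5 * rng.standard_normal(nominal.shape)
        out.append(scramble_with_u(nominal, spec.scram_range, u))
    return out


def compare_parameter_sets(a: Sequence[float], b: Sequence[float]) -> float:
    """RMS log-ratio divergence: sqrt(mean(log(a_i/b_i)^2)); 0 iff identical."""
    av, bv = np.asarray(a, float), np.asarray(b, float)
    if np.any(av <= 0) or np.any(bv <= 0):
        raise ValueError("parameter vectors must be positive")
    return float(np.sqrt(np.mean(np.log(av / bv) ** 2)))


# ---------------------------------------------------------------------------
# objective machinery
# ---------------------------------------------------------------------------

class _StopOptimization(Exception):
    pass


@dataclass
class OptResult:
    final_params: Dict[str, float]
    initial_cost: float
    final_cost: float
    n_evaluations: int
    wall_time: float
    converged: bool
    timed_out: bool
    seed: int
    method: Dict[str, object] = field(default_factory=dict)
    block_results: List["OptResult"] = field(default_factory=list)

    def to_json(self) -> dict:
        d = {
            "final_params": self.final_params,
            "initial_cost": self.initial_cost,
            "final_cost": self.final_cost,
            "n_evaluations": self.n_evaluations,
            "wall_time": self.wall_time,
            "converged": self.converged,
            "timed_out": self.timed_out,
            "seed": self.seed,
            "method": self.method,
        }
        if self.block_results:
            d["block_results"] = [b.to_json() for b in self.block_results]
        return d


class _Objective:
    """WNRMS objective over a parameter space, with budget/timeout accounting."""

    def __init__(
        self,
        model: NetworkModel,
        space: ParamSpace,
        experiments: Sequence[ExperimentDef],
        weights: Optional[Sequence[float]] = None,
        clamps: Sequence[ClampSpec] = (),
        budget: Optional[int] = None,
        timeout: Optional[float] = None,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ) -> None:
        self.work = model.copy()
        self.space = space
        self.experiments = list(experiments)
        self.weights = list(weights) if weights is not None else None
        self.clamps = list(clamps)
        self.budget = budget
        self.timeout = timeout
        self.rtol, self.atol = rtol, atol
        self.n_evals = 0
        self.t0 = time.monotonic()
        self.best_theta: Optional[np.ndarray] = None
        self.best_cost = math.inf
        lo = np.array([b[0] for b in space.theta_bounds()])
        hi = np.array([b[1] for b in space.theta_bounds()])
        self._lo, self._hi = lo, hi

    def __call__(self, theta: np.ndarray) -> float:
        if self.budget is not None and self.n_evals >= self.budget:
            raise _StopOptimization
        if self.timeout is not None and time.monotonic() - self.t0 > self.timeout:
            raise _StopOptimization
        theta = np.clip(np.asarray(theta, float), self._lo, self._hi)
        self.space.apply(self.work, self.space.from_theta(theta))
        self.n_evals += 1
        try:
            cost = score_model(
                self.work, self.experiments, clamps=self.clamps,
                weights=self.weights, rtol=self.rtol, atol=self.atol,
            ).wnrms
        except Exception:
            cost = 1e9  # integration failure at a bad parameter point
        if cost < self.best_cost:
            self.best_cost = cost
            self.best_theta = theta.copy()
        return cost


def _run_minimize(
    obj: _Objective,
    theta0: np.ndarray,
    algorithm: str,
    tolerance: float,
) -> Tuple[bool, bool]:
    """Run scipy.optimize.minimize; returns (converged, timed_out)."""
    method = _ALGORITHMS[algorithm]
    bounds = obj.space.theta_bounds() if method != "BFGS" else None
    options: Dict[str, object] = {}
    if obj.budget is not None:
        if method == "COBYLA":
            options["maxiter"] = obj.budget
        elif method == "Nelder-Mead":
            options["maxfev"] = obj.budget
        else:
            options["maxiter"] = obj.budget
    timed_out = False
    try:
        res = sciopt.minimize(
            obj, theta0, method=method, bounds=bounds, tol=tolerance, options=options
        )
        converged = bool(res.success)
    except _StopOptimization:
        converged = False
        timed_out = obj.timeout is not None and (
            time.monotonic() - obj.t0 > obj.timeout
        )
    return converged, timed_out


def optimize_flat(
    model: NetworkModel,
    params: ParamSpace,
    experiments: Sequence[ExperimentDef],
    algorithm: str = "COBYLA",
    budget: Optional[int] = None,
    timeout: Optional[float] = None,
    tolerance: float = 1e-6,
    weights: Optional[Sequence[float]] = None,
    clamps: Sequence[ClampSpec] = (),
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> OptResult:
    """Jointly minimize WNRMS over all parameters (the flat baseline method)."""
    if not params.refs:
        raise ValueError("empty parameter space")
    t_start = time.monotonic()
    obj = _Objective(model, params, experiments, weights=weights, clamps=clamps,
                     budget=budget, timeout=timeout, rtol=rtol, atol=atol)
    theta0 = params.to_theta(params.values(model))
    theta0 = np.clip(theta0, obj._lo, obj._hi)
    initial_cost = obj(theta0) if budget != 0 else _cost_only(obj, theta0)
    if not math.isfinite(initial_cost):
        raise ValueError("objective not finite at the starting point")
    converged = False
    timed_out = False
    if budget != 0:
        converged, timed_out = _run_minimize(obj, theta0, algorithm, tolerance)
    best_theta = obj.best_theta if obj.best_theta is not None else theta0
    values = params.from_theta(best_theta)
    final = model.copy()
    params.apply(final, values)
    return OptResult(
        final_params={r.path: float(v) for r, v in zip(params.refs, values)},
        initial_cost=float(initial_cost),
        final_cost=float(min(obj.best_cost, initial_cost)),
        n_evaluations=obj.n_evals,
        wall_time=time.monotonic() - t_start,
        converged=converged,
        timed_out=timed_out,
        seed=seed,
        method={"name": "flat", "algorithm": algorithm, "budget": budget},
    )


def _cost_only(obj: _Objective, theta: np.ndarray) -> float:
    saved = obj.budget
    obj.budget = None
    try:
        return obj(theta)
    finally:
        obj.budget = saved


# ---------------------------------------------------------------------------
# hierarchical method
# ---------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """One optimization unit: a named block with its parameters and experiments."""

    name: str
    param_paths: List[str]
    experiments: List[ExperimentDef]
    weights: Optional[List[float]] = None
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    clamps: List[ClampSpec] = field(default_factory=list)


def block_specs_from_decomposition(
    model: NetworkModel,
    decomposition: Decomposition,
    experiments: Sequence[ExperimentDef],
) -> List[List[BlockSpec]]:
    """Derive per-level block problems from a decomposition.

    A block's tunable parameters are the local parameters of reactions first
    appearing at its level (J_l minus J_{l-1}) that touch the block's members;
    its experiments are those whose readouts all lie in I_l with at least one
    inside the block.  Experiments with readouts outside every I set (or
    direct-parameter estimates naming a block parameter) follow the parameter.
    """
    levels: Dict[int, List[BlockSpec]] = {}
    J_prev: Set[str] = set()
    dyn_blocks = sorted(decomposition.dynamic_blocks(), key=lambda b: (b.level, b.id))
    level_values = sorted({b.level for b in dyn_blocks})
    I_sets = decomposition.nested_species_sets
    J_sets = decomposition.nested_reaction_sets

    for li, lvl in enumerate(level_values):
        I_l = I_sets[li] if li < len(I_sets) else set()
        J_l = J_sets[li] if li < len(J_sets) else set()
        new_rxns = J_l - J_prev
        for blk in [b for b in dyn_blocks if b.level == lvl]:
            paths: List[str] = []
            for rid in sorted(new_rxns):
                rxn = model.get_reaction(rid)
                touched = set(rxn.reactant_stoich) | set(rxn.product_stoich)
                if touched & blk.members:
                    paths += [f"{rid}.{p}" for p in sorted(rxn.parameters)]
            exps = []
            for exp in experiments:
                entities = {ro.entity for ro in exp.readouts}
                if exp.protocol == "direct_parameter":
                    if entities & set(paths):
                        exps.append(exp)
                    continue
                if entities <= I_l and entities & set(blk.members):
                    exps.append(exp)
            levels.setdefault(lvl, []).append(
                BlockSpec(name=blk.id, param_paths=paths, experiments=exps)
            )
        J_prev = J_l
    return [levels[l] for l in sorted(levels)]


def make_dependent_input_clamps(
    model: NetworkModel,
    decomposition: Decomposition,
    block,
    experiments: Sequence[ExperimentDef],
) -> Tuple[List[ClampSpec], List[str]]:
    """Clamp feedback inputs of a block to their observed time courses.

    For every interaction-graph edge u -> v with v inside the block and u in a
    strictly higher (not yet optimized) level, emit a ClampSpec built from the
    time-series observations of u, if any exist.  Returns (clamps, uncovered):
    feedback species without data are reported and left free.
    """
    graph = build_interaction_graph(model)
    level_of: Dict[str, int] = {}
    for b in decomposition.dynamic_blocks():
        for sid in b.members:
            level_of[sid] = b.level
    feedback_sources: Set[str] = set()
    for u, v in graph.edges:
        if v in block.members and u in level_of and level_of[u] > block.level:
            feedback_sources.add(u)
    clamps: List[ClampSpec] = []
    uncovered: List[str] = []
    for sid in sorted(feedback_sources):
        series: List[Tuple[float, float]] = []
        for exp in experiments:
            if exp.protocol != "timeseries":
                continue
            for ro in exp.readouts:
                if ro.entity == sid:
                    series += [(float(p[0]), float(p[1])) for p in ro.points]
        series = sorted(set(series))
        if len(series) >= 2:
            clamps.append(ClampSpec(entity=sid, time_series=series))
        else:
            uncovered.append(sid)
    return clamps, uncovered


def optimize_hierarchical(
    model: NetworkModel,
    decomposition: Optional[Decomposition] = None,
    block_configs: Optional[List[List[BlockSpec]]] = None,
    experiments: Optional[Sequence[ExperimentDef]] = None,
    algorithm: str = "COBYLA",
    budget_per_block: Optional[int] = None,
    timeout: Optional[float] = None,
    tolerance: float = 1e-6,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    scale: str = "log",
    default_fold: float = DEFAULT_BOUND_FOLD,
) -> OptResult:
    """Nested hierarchical optimization: levels in order, lower levels frozen.

    Within a level each block is optimized independently against its own
    experiments; optimized parameters are then frozen before the next level.
    Blocks without applicable experiments or parameters pass through
    unoptimized with a note in the result metadata.
    """
    t_start = time.monotonic()
    if block_configs is None:
        if decomposition is None or experiments is None:
            raise ValueError("need either block_configs or decomposition+experiments")
        block_configs = block_specs_from_decomposition(model, decomposition, experiments)
    all_exps = list(experiments) if experiments is not None else [
        e for lvl in block_configs for b in lvl for e in b.experiments
    ]

    work = model.copy()
    block_results: List[OptResult] = []
    notes: List[str] = []
    total_evals = 0
    any_timeout = False

    for li, level in enumerate(block_configs):
        for bi, blk in enumerate(level):
            if not blk.param_paths:
                notes.append(f"block {blk.name}: no tunable parameters, passed through")
                continue
            if not blk.experiments:
                notes.append(f"block {blk.name}: no applicable experiments, passed through")
                continue
            space = ParamSpace.from_paths(
                work, blk.param_paths, bounds=blk.bounds, scale=scale,
                default_fold=default_fold,
            )
            res = optimize_flat(
                work, space, blk.experiments,
                algorithm=algorithm, budget=budget_per_block, timeout=timeout,
                tolerance=tolerance, weights=blk.weights, clamps=blk.clamps,
                seed=derive_seed(seed, li, bi), rtol=rtol, atol=atol,
            )
            if (
                res.n_evaluations > 1
                and res.final_cost == res.initial_cost
                and res.initial_cost > 0
            ):
                notes.append(f"block {blk.name}: objective insensitive to parameters")
            res.method = {"name": "hierarchical-block", "block": blk.name,
                          "level": li, "algorithm": algorithm}
            block_results.append(res)
            total_evals += res.n_evaluations
            any_timeout |= res.timed_out
            for path, val in res.final_params.items():
                set_parameter_inplace(work, ParameterRef(path), val)  # freeze

    all_paths = [p for lvl in block_configs for b in lvl for p in b.param_paths]
    final_params = {
        p: get_parameter(work, ParameterRef(p)) for p in all_paths
    }
    initial_cost = score_model(model, all_exps, rtol=rtol, atol=atol).wnrms
    final_cost = score_model(work, all_exps, rtol=rtol, atol=atol).wnrms
    return OptResult(
        final_params=final_params,
        initial_cost=float(initial_cost),
        final_cost=float(final_cost),
        n_evaluations=total_evals,
        wall_time=time.monotonic() - t_start,
        converged=all(b.converged for b in block_results) if block_results else False,
        timed_out=any_timeout,
        seed=seed,
        method={"name": "hierarchical", "algorithm": algorithm,
                "budget_per_block": budget_per_block, "notes": notes},
        block_results=block_results,
    )


# ---------------------------------------------------------------------------
# multistart (initScram)
# ---------------------------------------------------------------------------

def _all_param_paths(block_configs: List[List[BlockSpec]]) -> List[str]:
    return [p for lvl in block_configs for b in lvl for p in b.param_paths]


def _apply_vector(model: NetworkModel, paths: Sequence[str], values: Sequence[float]):
    out = model.copy()
    for p, v in zip(paths, values):
        set_parameter_inplace(out, ParameterRef(p), float(v))
    return out


def init_scram(
    model: NetworkModel,
    block_configs: List[List[BlockSpec]],
    spec: ScrambleSpec,
    n_rounds: int = 1,
    algorithm: str = "COBYLA",
    budget_per_block: Optional[int] = None,
    timeout: Optional[float] = None,
    tolerance: float = 1e-6,
    master_seed: int = 0,
    include_nominal: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    n_jobs: int = 1,
) -> List[OptResult]:
    """Multistart hierarchical optimization from a scrambled population.

    The population holds ``spec.count`` starting models: the nominal model
    itself (when ``include_nominal``) plus log-scrambled variants.  Each is
    optimized by the hierarchical method; successive rounds re-scramble around
    the incumbent best.  Returns all results ranked by final cost (the full
    cost distribution).  Deterministic for a fixed master seed, independent of
    ``n_jobs``.
    """
    if spec.count < 1:
        raise ValueError("population size must be >= 1")
    paths = _all_param_paths(block_configs)
    nominal = np.array([get_parameter(model, ParameterRef(p)) for p in paths])

    results: List[OptResult] = []
    incumbent = nominal
    incumbent_model = model
    for rnd in range(n_rounds):
        pop_spec = ScrambleSpec(
            scram_range=spec.scram_range, distribution=spec.distribution,
            count=spec.count, seed=derive_seed(master_seed, 1000 + rnd),
        )
        starts = scramble(incumbent, pop_spec)
        if include_nominal:
            starts[0] = incumbent.copy()

        def _one(k: int) -> OptResult:
            start_model = _apply_vector(incumbent_model, paths, starts[k])
            res = optimize_hierarchical(
                start_model, block_configs=block_configs, algorithm=algorithm,
                budget_per_block=budget_per_block, timeout=timeout,
                tolerance=tolerance, seed=derive_seed(master_seed, rnd, k),
                rtol=rtol, atol=atol,
            )
            res.method = {"name": "initScram", "round": rnd, "member": k,
                          "algorithm": algorithm}
            return res

        if n_jobs > 1:
            from joblib import Parallel, delayed

            round_results = Parallel(n_jobs=n_jobs)(
                delayed(_one)(k) for k in range(spec.count)
            )
        else:
            round_results = [_one(k) for k in range(spec.count)]
        if all(r.timed_out for r in round_results):
            raise RuntimeError("all multistart runs timed out")
        results.extend(round_results)
        best = min(results, key=lambda r: r.final_cost)
        incumbent = np.array([best.final_params[p] for p in paths])
        incumbent_model = _apply_vector(model, paths, incumbent)
    return sorted(results, key=lambda r: r.final_cost)


# ---------------------------------------------------------------------------
# staged Monte Carlo (hossMC)
# ---------------------------------------------------------------------------

def hoss_mc(
    model: NetworkModel,
    block_configs: List[List[BlockSpec]],
    S: int = 40,
    N: int = 5,
    scram_range: float = 2.0,
    distribution: str = "uniform",
    algorithm: str = "COBYLA",
    budget_per_block: Optional[int] = None,
    timeout: Optional[float] = None,
    tolerance: float = 1e-6,
    master_seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    n_jobs: int = 1,
) -> List[OptResult]:
    """Multi-stage Monte Carlo over the hierarchy; returns the top N models.

    Per level: each of the N carried parents spawns ceil(S/N) variants whose
    block parameters are scrambled and optimized independently (one elementary
    minimization per block).  Within a parent, variant results are rank-paired
    across blocks (block costs are additive in the combined WNRMS, so
    best-with-best is optimal), and the best N merged models over all parents
    are carried forward.  The final ranking uses the full-model WNRMS.
    """
    if not (S >= N >= 1):
        raise ValueError("need S >= N >= 1")
    all_exps = [e for lvl in block_configs for b in lvl for e in b.experiments]
    per_parent = math.ceil(S / N)

    carried: List[NetworkModel] = [model.copy()]
    carried_seeds = [master_seed]

    for li, level in enumerate(block_configs):
        active_blocks = [b for b in level if b.param_paths and b.experiments]
        passive = [b for b in level if b not in active_blocks]
        if not active_blocks:
            continue
        candidates: List[Tuple[float, NetworkModel]] = []
        for pi, parent in enumerate(carried):
            n_var = per_parent if pi < len(carried) else 0
            # per block: optimize each scrambled variant, rank by block cost
            ranked_per_block: List[List[Tuple[float, Dict[str, float]]]] = []
            for bi, blk in enumerate(active_blocks):
                space = ParamSpace.from_paths(parent, blk.param_paths,
                                              bounds=blk.bounds)
                nominal = space.values(parent)
                sspec = ScrambleSpec(
                    scram_range=scram_range, distribution=distribution,
                    count=n_var, seed=derive_seed(master_seed, li, pi, bi),
                )
                starts = scramble(nominal, sspec)
                if starts:
                    starts[0] = nominal.copy()  # keep the unscrambled parent

                def _opt_variant(v: int) -> Tuple[float, Dict[str, float]]:
                    m = parent.copy()
                    space.apply(m, starts[v])
                    res = optimize_flat(
                        m, ParamSpace.from_paths(m, blk.param_paths, bounds=blk.bounds),
                        blk.experiments, algorithm=algorithm,
                        budget=budget_per_block, timeout=timeout,
                        tolerance=tolerance, weights=blk.weights, clamps=blk.clamps,
                        seed=derive_seed(master_seed, li, pi, bi, v),
                        rtol=rtol, atol=atol,
                    )
                    return res.final_cost, res.final_params

                if n_jobs > 1:
                    from joblib import Parallel, delayed

                    variants = Parallel(n_jobs=n_jobs)(
                        delayed(_opt_variant)(v) for v in range(n_var)
                    )
                else:
                    variants = [_opt_variant(v) for v in range(n_var)]
                ranked_per_block.append(sorted(variants, key=lambda t: t[0]))
            # rank-pair across blocks within this parent
            for rank in range(min(len(r) for r in ranked_per_block)):
                merged = parent.copy()
                cost_sq_sum, w_sum = 0.0, 0.0
                for bi, blk in enumerate(active_blocks):
                    c, pvals = ranked_per_block[bi][rank]
                    for path, val in pvals.items():
                        set_parameter_inplace(merged, ParameterRef(path), val)
                    w = sum(blk.weights) if blk.weights else len(blk.experiments)
                    cost_sq_sum += w * c * c
                    w_sum += w
                level_cost = math.sqrt(cost_sq_sum / w_sum) if w_sum else math.inf
                candidates.append((level_cost, merged))
        if not candidates:
            continue
        candidates.sort(key=lambda t: t[0])
        carried = [m for _, m in candidates[:N]]
        if len(carried) < N:
            carried += [carried[-1].copy() for _ in range(N - len(carried))]

    results = []
    for k, m in enumerate(carried):
        paths = _all_param_paths(block_configs)
        cost = score_model(m, all_exps, rtol=rtol, atol=atol).wnrms if all_exps else math.inf
        results.append(
            OptResult(
                final_params={p: get_parameter(m, ParameterRef(p)) for p in paths},
                initial_cost=math.nan,
                final_cost=float(cost),
                n_evaluations=0,
                wall_time=0.0,
                converged=True,
                timed_out=False,
                seed=derive_seed(master_seed, 9999, k),
                method={"name": "hossMC", "rank": k, "S": S, "N": N,
                        "scram_range": scram_range, "algorithm": algorithm},
            )
        )
    return sorted(results, key=lambda r: r.final_cost)[: N]
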