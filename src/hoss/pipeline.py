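"""Pipeline orchestration: hoss-config-1 parsing, dispatch, reproducible outputs.

A single JSON configuration file names the model, the optimization method
(flat, hierarchical, initScram, hossMC), the algorithm and its budgets, the
scramble settings, a master seed, and either an explicit hierarchy (levels of
blocks, each with experiment files + weights and parameter paths) or
auto-decomposition options.  Running a config produces a results directory
with ranked optimized models, cost tables (CSV), per-run JSON results, and a
provenance record sufficient to re-run bit-reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .decompose import (
    Decomposition,
    DecompositionOptions,
    auto_decompose,
    check_autonomous_pair,
    write_decomposition_report,
)
from .model import NetworkModel, ParameterRef, get_parameter, load_model, write_model
from .optimize import (
    BlockSpec,
    OptResult,
    ParamSpace,
    ScrambleSpec,
    block_specs_from_decomposition,
    compare_parameter_sets,
    hoss_mc,
    init_scram,
    optimize_flat,
    optimize_hierarchical,
)
from .schemas import validate_config
from .scoring import ExperimentDef, read_experiment, score_model

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    doc: dict
    base_dir: Path

    @property
    def method(self) -> str:
        return self.doc["method"]

    @property
    def seed(self) -> int:
        return int(self.doc.get("seed", 0))

    @property
    def algorithm(self) -> str:
        return self.doc.get("algorithm", "COBYLA")

    @property
    def output_dir(self) -> Path:
        return self.base_dir / self.doc.get("output_dir", "results")

    def model_path(self) -> Tuple[Path, Optional[str]]:
        m = self.doc["model"]
        return self.base_dir / m["path"], m.get("format")


def load_config(path: str) -> PipelineConfig:
    p = Path(path)
    with open(p) as fh:
        doc = json.load(fh)
    validate_config(doc)
    cfg = PipelineConfig(doc=doc, base_dir=p.parent)
    # existence / resolvability checks beyond the schema
    model_path, fmt = cfg.model_path()
    if not model_path.exists():
        raise FileNotFoundError(f"model file not found: {model_path}")
    model = load_model(str(model_path), fmt)
    for level in doc.get("hierarchy", []):
        for blk in level["blocks"]:
            for e in blk.get("experiments", []):
                ep = cfg.base_dir / e["path"]
                if not ep.exists():
                    raise FileNotFoundError(f"experiment file not found: {ep}")
            for path_ in blk.get("params", []):
                ParameterRef(path_)._resolve(model)
    for e in doc.get("auto_hierarchy", {}).get("experiments", []):
        ep = cfg.base_dir / e["path"]
        if not ep.exists():
            raise FileNotFoundError(f"experiment file not found: {ep}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_block_configs(
    cfg: PipelineConfig, model: NetworkModel
) -> Tuple[List[List[BlockSpec]], List[ExperimentDef], Optional[Decomposition]]:
    doc = cfg.doc
    if "hierarchy" in doc:
        block_configs: List[List[BlockSpec]] = []
        all_exps: List[ExperimentDef] = []
        warnings: List[str] = []
        seen_species: set = set()
        for level in doc["hierarchy"]:
            specs = []
            for blk in level["blocks"]:
                exps, weights = [], []
                for e in blk.get("experiments", []):
                    exp = read_experiment(str(cfg.base_dir / e["path"]))
                    exps.append(exp)
                    weights.append(float(e.get("weight", exp.weight)))
                bounds = {
                    k: (float(v[0]), float(v[1]))
                    for k, v in blk.get("bounds", {}).items()
                }
                specs.append(
                    BlockSpec(
                        name=blk["name"],
                        param_paths=list(blk.get("params", [])),
                        experiments=exps,
                        weights=weights or None,
                        bounds=bounds or None,
                    )
                )
                all_exps.extend(exps)
            block_configs.append(specs)
        return block_configs, all_exps, None

    auto = doc["auto_hierarchy"]
    exps = []
    weights = []
    for e in auto.get("experiments", []):
        exp = read_experiment(str(cfg.base_dir / e["path"]))
        if "weight" in e:
            exp.weight = float(e["weight"])
        exps.append(exp)
    opts = DecompositionOptions(
        r=auto.get("r", 1),
        use_agony=auto.get("use_agony", True),
        qss_reduce=auto.get("qss_reduce", False),
        irreversible_reactions=auto.get("irreversibility", []),
    )
    decomp = auto_decompose(model, opts)
    block_configs = block_specs_from_decomposition(model, decomp, exps)
    return block_configs, exps, decomp


def _check_explicit_hierarchy(
    model: NetworkModel, block_configs: List[List[BlockSpec]]
) -> List[str]:
    """Warn when an explicit hierarchy violates the autonomous-pair conditions."""
    warnings: List[str] = []
    I: set = set()
    J: set = set()
    sids = set(model.species_ids())
    for level in block_configs:
        for blk in level:
            for path in blk.param_paths:
                head = path.split(".", 1)[0]
                if head in sids:
                    I.add(head)
                else:
                    J.add(head)
        for rid in list(J):
            try:
                rxn = model.get_reaction(rid)
            except KeyError:
                continue
            I |= (set(rxn.reactant_stoich) | set(rxn.product_stoich)) - model.buffered_ids()
        for v in check_autonomous_pair(model, I, J):
            warnings.append(v)
    return warnings


def run_pipeline(cfg: PipelineConfig, n_jobs: Optional[int] = None) -> Path:
    """Execute the configured method end to end; returns the output directory."""
    t0 = time.monotonic()
    doc = cfg.doc
    model_path, fmt = cfg.model_path()
    model = load_model(str(model_path), fmt)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = [f"pipeline method={cfg.method} seed={cfg.seed}"]

    block_configs, experiments, decomp = _load_block_configs(cfg, model)
    if "hierarchy" in doc:
        for w in _check_explicit_hierarchy(model, block_configs):
            log_lines.append(f"WARNING explicit hierarchy: {w}")
    if decomp is not None:
        write_decomposition_report(decomp, str(out / "decomposition.json"))

    algorithm = cfg.algorithm
    tolerance = float(doc.get("tolerance", 1e-6))
    budget = doc.get("budget")
    timeout = doc.get("timeout")
    scr = doc.get("scramble", {})
    sspec = ScrambleSpec(
        scram_range=float(scr.get("range", 2.0)),
        distribution=scr.get("distribution", "uniform"),
        count=int(scr.get("count", 20)),
        seed=cfg.seed,
    )
    top_n = int(doc.get("topN", 5))
    jobs = n_jobs if n_jobs is not None else int(doc.get("n_jobs", 1))

    ranked: List[OptResult]
    if cfg.method == "flat":
        paths = [p for lvl in block_configs for b in lvl for p in b.param_paths]
        bounds: Dict[str, Tuple[float, float]] = {}
        for lvl in block_configs:
            for b in lvl:
                if b.bounds:
                    bounds.update(b.bounds)
        space = ParamSpace.from_paths(model, paths, bounds=bounds or None)
        res = optimize_flat(
            model, space, experiments, algorithm=algorithm, budget=budget,
            timeout=timeout, tolerance=tolerance, seed=cfg.seed,
        )
        ranked = [res]
    elif cfg.method == "hierarchical":
        res = optimize_hierarchical(
            model, block_configs=block_configs, experiments=experiments,
            algorithm=algorithm, budget_per_block=budget, timeout=timeout,
            tolerance=tolerance, seed=cfg.seed,
        )
        ranked = [res]
    elif cfg.method == "initScram":
        ranked = init_scram(
            model, block_configs, sspec, n_rounds=int(scr.get("rounds", 1)),
            algorithm=algorithm, budget_per_block=budget, timeout=timeout,
            tolerance=tolerance, master_seed=cfg.seed, n_jobs=jobs,
        )
    elif cfg.method == "hossMC":
        ranked = hoss_mc(
            model, block_configs, S=sspec.count, N=top_n,
            scram_range=sspec.scram_range, distribution=sspec.distribution,
            algorithm=algorithm, budget_per_block=budget, timeout=timeout,
            tolerance=tolerance, master_seed=cfg.seed, n_jobs=jobs,
        )
    else:  # pragma: no cover - schema forbids
        raise ValueError(f"unknown method {cfg.method!r}")

    # ---- outputs -------------------------------------------------------
    import pandas as pd

    rows = []
    for rank, r in enumerate(ranked):
        rows.append(
            {"rank": rank, "initial_cost": r.initial_cost, "final_cost": r.final_cost,
             "n_evaluations": r.n_evaluations, "converged": r.converged,
             "timed_out": r.timed_out, "seed": r.seed}
        )
        m = model.copy()
        for path, val in r.final_params.items():
            from .model import set_parameter_inplace

            set_parameter_inplace(m, ParameterRef(path), val)
        write_model(m, str(out / f"model_rank{rank}.json"), "native")
        with open(out / f"result_rank{rank}.json", "w") as fh:
            json.dump(r.to_json(), fh, indent=1, sort_keys=True)
    pd.DataFrame(rows).to_csv(out / "costs.csv", index=False, float_format="%.12g")

    if len(ranked) > 1:
        paths = sorted(ranked[0].final_params)
        div_rows = []
        for i in range(len(ranked)):
            for j in range(i + 1, len(ranked)):
                a = [ranked[i].final_params[p] for p in paths]
                b = [ranked[j].final_params[p] for p in paths]
                try:
                    d = compare_parameter_sets(a, b)
                except ValueError:
                    d = float("nan")
                div_rows.append({"i": i, "j": j, "rms_log_divergence": d})
        pd.DataFrame(div_rows).to_csv(
            out / "parameter_divergence.csv", index=False, float_format="%.12g"
        )

    provenance = {
        "tool_version": __version__,
        "config": doc,
        "model_sha256": _sha256(model_path),
        "master_seed": cfg.seed,
        "method": cfg.method,
        "n_results": len(ranked),
        "total_evaluations": sum(r.n_evaluations for r in ranked),
        "wall_time_s": time.monotonic() - t0,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    log_lines.append(f"done in {provenance['wall_time_s']:.1f}s, "
                     f"best cost {ranked[0].final_cost:.6g}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
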