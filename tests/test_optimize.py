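import math

import numpy as np
import pytest
from scipy import stats

from hoss.decompose import auto_decompose
from hoss.model import ParameterRef, get_parameter, set_parameter_inplace
from hoss.optimize import (
    BlockSpec,
    ParamSpace,
    ScrambleSpec,
    block_specs_from_decomposition,
    compare_parameter_sets,
    derive_seed,
    hoss_mc,
    init_scram,
    make_dependent_input_clamps,
    optimize_flat,
    optimize_hierarchical,
    scramble,
    scramble_with_u,
)
from hoss.synth import generate_synthetic_cascade, generate_synthetic_experiments


@pytest.fixture(scope="module")
def cascade_setup(cascade3):
    model, truth, exps = cascade3
    decomp = auto_decompose(model)
    bcs = block_specs_from_decomposition(model, decomp, exps)
    return model, truth, exps, decomp, bcs


def scrambled_start(model, truth, scram_range=2.0, seed=0):
    paths = sorted(truth)
    vals = scramble(
        np.array([truth[p] for p in paths]),
        ScrambleSpec(scram_range=scram_range, count=1, seed=seed),
    )[0]
    out = model.copy()
    for p, v in zip(paths, vals):
        set_parameter_inplace(out, ParameterRef(p), v)
    return out, paths


# ---------------------------------------------------------------------------
# scrambling
# ---------------------------------------------------------------------------

def test_scramble_formula_endpoints():
    p = np.array([1.0, 4.0])
    assert scramble_with_u(p, 2.0, np.zeros(2)) == pytest.approx(p / 2.0)
    assert scramble_with_u(p, 2.0, np.ones(2)) == pytest.approx(p * 2.0)
    assert scramble_with_u(np.array([1.0]), 2.0, np.array([0.5]))[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        scramble_with_u(np.array([-1.0]), 2.0, np.array([0.5]))


def test_scramble_uniform_is_log_uniform():
    """log(p/nominal) is uniform on [-log r, log r] (KS test at n = 1e4)."""
    for r in (1.2, 2.0, 5.0):
        spec = ScrambleSpec(scram_range=r, count=1, seed=123)
        draws = scramble(np.ones(10_000), spec)[0]
        logs = np.log(draws)
        stat = stats.kstest(logs, stats.uniform(-math.log(r), 2 * math.log(r)).cdf)
        assert stat.pvalue > 0.01, (r, stat.pvalue)
        assert np.all(np.abs(logs) <= math.log(r) + 1e-12)


def test_scramble_deterministic():
    spec = ScrambleSpec(scram_range=3.0, count=5, seed=7)
    a = scramble(np.ones(4), spec)
    b = scramble(np.ones(4), spec)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_compare_parameter_sets():
    a = np.array([1.0, 2.0, 3.0])
    assert compare_parameter_sets(a, a) == 0.0
    assert compare_parameter_sets(2 * a, a) == pytest.approx(math.log(2.0))
    assert compare_parameter_sets(a, 2 * a) == pytest.approx(math.log(2.0))
    with pytest.raises(ValueError):
        compare_parameter_sets(a, -a)


def test_scramble_divergence_monotone_in_range():
    rng_means = []
    for r in (1.2, 2.0, 5.0):
        spec = ScrambleSpec(scram_range=r, count=50, seed=11)
        pop = scramble(np.ones(8), spec)
        rng_means.append(np.mean([compare_parameter_sets(v, np.ones(8)) for v in pop]))
    assert rng_means[0] < rng_means[1] < rng_means[2]


# ---------------------------------------------------------------------------
# flat method
# ---------------------------------------------------------------------------

def test_flat_recovers_one_parameter(cascade3):
    model, truth, exps = cascade3
    start = model.copy()
    set_parameter_inplace(start, ParameterRef("act_1_1.kact"),
                          truth["act_1_1.kact"] * 3.0)
    space = ParamSpace.from_paths(start, ["act_1_1.kact"])
    res = optimize_flat(start, space, exps[:1], budget=200)
    assert res.final_params["act_1_1.kact"] == pytest.approx(
        truth["act_1_1.kact"], rel=0.01
    )
    assert res.final_cost <= res.initial_cost


def test_flat_budget_zero_returns_initial(cascade_setup):
    model, truth, exps, _, _ = cascade_setup
    space = ParamSpace.from_paths(model, sorted(truth))
    res = optimize_flat(model, space, exps, budget=0)
    assert res.n_evaluations <= 1
    assert res.final_cost == res.initial_cost
    assert res.final_params == {p: get_parameter(model, ParameterRef(p))
                                for p in sorted(truth)}


def test_flat_budget_is_hard_cap(cascade_setup):
    model, truth, exps, _, _ = cascade_setup
    start, _ = scrambled_start(model, truth, seed=3)
    space = ParamSpace.from_paths(start, sorted(truth))
    res = optimize_flat(start, space, exps, budget=25)
    assert 0 < res.n_evaluations <= 25


# ---------------------------------------------------------------------------
# hierarchical method
# ---------------------------------------------------------------------------

def test_hierarchical_recovery_two_tier():
    model, truth = generate_synthetic_cascade(2, 1, seed=13)
    exps = generate_synthetic_experiments(model, truth, noise_sd=0.0, seed=0)
    decomp = auto_decompose(model)
    bcs = block_specs_from_decomposition(model, decomp, exps)
    start, paths = scrambled_start(model, truth, seed=1)
    res = optimize_hierarchical(start, block_configs=bcs, budget_per_block=800)
    for p in paths:
        assert res.final_params[p] == pytest.approx(truth[p], rel=0.01), p
    assert res.final_cost < 1e-3


def test_hierarchical_single_level_equals_flat(cascade_setup):
    model, truth, exps, _, _ = cascade_setup
    start, paths = scrambled_start(model, truth, seed=5)
    single = [[BlockSpec(name="all", param_paths=paths, experiments=list(exps))]]
    rh = optimize_hierarchical(start, block_configs=single, budget_per_block=80)
    space = ParamSpace.from_paths(start, paths)
    rf = optimize_flat(start, space, exps, budget=80)
    assert rh.final_cost == pytest.approx(rf.final_cost, rel=1e-12)
    for p in paths:
        assert rh.final_params[p] == pytest.approx(rf.final_params[p], rel=1e-12)


def test_hierarchical_freezes_lower_levels(cascade_setup):
    """After a level finishes, its parameters never move again."""
    model, truth, exps, _, bcs = cascade_setup
    start, _ = scrambled_start(model, truth, seed=2)
    res = optimize_hierarchical(start, block_configs=bcs, budget_per_block=60)
    for blk_res in res.block_results:
        for path, val in blk_res.final_params.items():
            assert res.final_params[path] == val


def test_hierarchical_block_without_experiments_passes_through(cascade_setup):
    model, truth, exps, _, bcs = cascade_setup
    trimmed = [[BlockSpec(name=b.name, param_paths=b.param_paths,
                          experiments=b.experiments if i == 0 else [])
                for b in lvl] for i, lvl in enumerate(bcs)]
    start, _ = scrambled_start(model, truth, seed=4)
    res = optimize_hierarchical(start, block_configs=trimmed, budget_per_block=40)
    notes = res.method["notes"]
    assert any("no applicable experiments" in n for n in notes)
    for lvl in trimmed[1:]:
        for b in lvl:
            for p in b.param_paths:
                assert res.final_params[p] == get_parameter(start, ParameterRef(p))


def test_dependent_input_clamps():
    model, truth = generate_synthetic_cascade(
        3, 1, feedback={"strength": 1.0}, seed=5
    )
    exps = generate_synthetic_experiments(model, truth, noise_sd=0.0, seed=0)
    decomp = auto_decompose(model)
    low = next(b for b in decomp.dynamic_blocks() if "X11" in b.members)
    clamps, uncovered = make_dependent_input_clamps(model, decomp, low, exps)
    assert [c.entity for c in clamps] == ["X31a"]
    assert uncovered == []
    # without observations of the feedback species, it is reported uncovered
    clamps2, uncovered2 = make_dependent_input_clamps(
        model, decomp, low, [e for e in exps if e.readouts[0].entity != "X31a"]
    )
    assert clamps2 == [] and uncovered2 == ["X31a"]


def test_no_feedback_no_clamps(cascade_setup):
    model, truth, exps, decomp, _ = cascade_setup
    for blk in decomp.dynamic_blocks():
        clamps, uncovered = make_dependent_input_clamps(model, decomp, blk, exps)
        assert clamps == [] and uncovered == []


# ---------------------------------------------------------------------------
# multistart and staged Monte Carlo
# ---------------------------------------------------------------------------

def test_init_scram_deterministic_and_dominates_single_start(cascade_setup):
    model, truth, exps, _, bcs = cascade_setup
    start, _ = scrambled_start(model, truth, seed=8)
    spec = ScrambleSpec(scram_range=2.0, count=4, seed=0)
    pop1 = init_scram(start, bcs, spec, budget_per_block=60, master_seed=42)
    pop2 = init_scram(start, bcs, spec, budget_per_block=60, master_seed=42)
    assert [r.final_cost for r in pop1] == [r.final_cost for r in pop2]
    single = optimize_hierarchical(
        start, block_configs=bcs, budget_per_block=60,
        seed=derive_seed(42, 0, 0),
    )
    assert pop1[0].final_cost <= single.final_cost + 1e-15


def test_init_scram_rounds_monotone(cascade_setup):
    model, truth, exps, _, bcs = cascade_setup
    start, _ = scrambled_start(model, truth, seed=9)
    spec = ScrambleSpec(scram_range=2.0, count=3, seed=0)
    pop = init_scram(start, bcs, spec, n_rounds=2, budget_per_block=40, master_seed=1)
    round1 = [r for r in pop if r.method["round"] == 0]
    round2 = [r for r in pop if r.method["round"] == 1]
    best1 = min(r.final_cost for r in round1)
    best = min(r.final_cost for r in pop)
    assert best <= best1  # incumbent never worsens
    assert len(round2) == 3


def test_hoss_mc_n1_greedy(cascade_setup):
    model, truth, exps, _, bcs = cascade_setup
    start, _ = scrambled_start(model, truth, seed=10)
    out = hoss_mc(start, bcs, S=3, N=1, budget_per_block=40, master_seed=3)
    assert len(out) == 1
    assert out[0].final_cost < score(start, exps)


def score(model, exps):
    from hoss.scoring import score_model

    return score_model(model, exps).wnrms


def test_hoss_mc_returns_ranked_top_n(cascade_setup):
    model, truth, exps, _, bcs = cascade_setup
    start, _ = scrambled_start(model, truth, seed=11)
    out = hoss_mc(start, bcs, S=4, N=2, budget_per_block=40, master_seed=5)
    assert len(out) == 2
    assert out[0].final_cost <= out[1].final_cost


def test_derive_seed_stable():
    assert derive_seed(1, 2, 3) == derive_seed(1, 2, 3)
    assert derive_seed(1, 2, 3) != derive_seed(1, 3, 2)
    assert 0 <= derive_seed(12345, 9) < 2**31
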