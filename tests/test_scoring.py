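import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hoss.model import ParameterRef, set_parameter
from hoss.scoring import (
    CostReport,
    ExperimentDef,
    ExperimentFormatError,
    ReadoutSeries,
    neg_log_likelihood,
    nrms,
    read_experiment,
    score_model,
    wnrms,
    write_experiment,
)
from hoss.schemas import SchemaError
from hoss.synth import generate_synthetic_cascade, generate_synthetic_experiments


def ro(entity, points, normalization="max"):
    return ReadoutSeries(entity=entity, points=points, normalization=normalization)


# ---------------------------------------------------------------------------
# NRMS / WNRMS / likelihood
# ---------------------------------------------------------------------------

def test_nrms_hand_computed_values():
    assert nrms({"y": np.array([2.0])}, [ro("y", [[0, 2.0]])]) == 0.0
    # one point: y=2, prediction 1, m=2 -> |(2-1)/2| = 0.5
    assert nrms({"y": np.array([1.0])}, [ro("y", [[0, 2.0]])]) == pytest.approx(0.5)
    # y=(1,2), predictions (1,1), m=2 -> sqrt((0 + 0.25)/2)
    v = nrms({"y": np.array([1.0, 1.0])}, [ro("y", [[0, 1.0], [1, 2.0]])])
    assert v == pytest.approx(math.sqrt(0.125))


def test_nrms_errors():
    with pytest.raises(ExperimentFormatError):
        nrms({"y": np.array([1.0])}, [ro("y", [[0, 0.0]])])  # m = 0
    with pytest.raises(KeyError):
        nrms({}, [ro("y", [[0, 1.0]])])
    with pytest.raises(ValueError):
        nrms({"y": np.array([1.0, 2.0])}, [ro("y", [[0, 1.0]])])


def test_nrms_rescale_invariance():
    rng = np.random.default_rng(0)
    y = rng.uniform(0.5, 2.0, 6)
    pred = y + rng.normal(0, 0.1, 6)
    base = nrms({"y": pred}, [ro("y", [[k, v] for k, v in enumerate(y)])])
    scaled = nrms(
        {"y": 7.5 * pred}, [ro("y", [[k, 7.5 * v] for k, v in enumerate(y)])]
    )
    assert scaled == pytest.approx(base)


def test_wnrms_values():
    assert wnrms([0.37], [2.0]) == pytest.approx(0.37)  # single dataset identity
    assert wnrms([0.3, 0.4], [1.0, 1.0]) == pytest.approx(math.sqrt(0.125))
    with pytest.raises(ValueError):
        wnrms([0.3], [0.0])
    with pytest.raises(ValueError):
        wnrms([], [])


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0.0, 10.0),
            st.floats(0.01, 100.0),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_wnrms_bounded_by_min_max(pairs):
    values = [p[0] for p in pairs]
    weights = [p[1] for p in pairs]
    w = wnrms(values, weights)
    assert min(values) - 1e-12 <= w <= max(values) + 1e-12


def test_neg_log_likelihood_values():
    n = 5
    x = np.arange(1.0, n + 1)
    assert neg_log_likelihood(x, x, np.ones(n), np.ones(n)) == pytest.approx(
        n / 2 * math.log(2 * math.pi)
    )
    assert neg_log_likelihood([0.0], [1.0], [1.0], [1.0]) == pytest.approx(
        0.5 * (math.log(2 * math.pi) + 1.0)
    )
    # doubling sigma at zero residual adds log 2 per point
    l1 = neg_log_likelihood(x, x, np.ones(n), np.ones(n))
    l2 = neg_log_likelihood(x, x, np.ones(n), 2 * np.ones(n))
    assert l2 - l1 == pytest.approx(n * math.log(2.0))
    with pytest.raises(ValueError):
        neg_log_likelihood([1.0], [1.0], [1.0], [0.0])


# ---------------------------------------------------------------------------
# experiment I/O
# ---------------------------------------------------------------------------

def minimal_exp() -> ExperimentDef:
    return ExperimentDef(
        id="ts1",
        protocol="timeseries",
        settle_time=0.0,
        readouts=[ro("X11a", [[1.0, 0.4], [2.0, 0.5]])],
        weight=2.0,
        metadata={"citation": "synthetic"},
    )


def test_experiment_roundtrip_byte_stable(tmp_path):
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    exp = minimal_exp()
    write_experiment(exp, str(p1))
    again = read_experiment(str(p1))
    assert len(again.readouts) == 1 and again.weight == 2.0
    write_experiment(again, str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_experiment_schema_rejects_bad_weight(tmp_path):
    doc = {
        "format": "hoss-exp-1", "id": "x", "protocol": "timeseries", "weight": -1,
        "readouts": [{"entity": "A", "points": [[0, 1]]}],
    }
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(SchemaError, match="weight"):
        read_experiment(str(p))


def test_experiment_schema_rejects_unknown_protocol(tmp_path):
    doc = {
        "format": "hoss-exp-1", "id": "x", "protocol": "voltage_clamp",
        "readouts": [{"entity": "A", "points": [[0, 1]]}],
    }
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(SchemaError, match="protocol"):
        read_experiment(str(p))


def test_experiment_def_invariants():
    with pytest.raises(ExperimentFormatError):
        ExperimentDef(id="x", protocol="timeseries", readouts=[])
    with pytest.raises(ExperimentFormatError):
        ExperimentDef(
            id="x", protocol="timeseries", weight=0.0,
            readouts=[ro("A", [[0, 1.0]])],
        )


# ---------------------------------------------------------------------------
# scoring models
# ---------------------------------------------------------------------------

def test_score_truth_is_zero(cascade3):
    model, truth, exps = cascade3
    report = score_model(model, exps)
    assert report.wnrms < 1e-6
    assert report.n_skipped == 0


def test_score_perturbed_parameter_increases_cost(cascade3):
    model, truth, exps = cascade3
    worse = set_parameter(
        model, ParameterRef("act_1_1.kact"), truth["act_1_1.kact"] * 10
    )
    assert score_model(worse, exps).wnrms > 1e-2


def test_score_weighted_combination_matches_hand_computation(cascade3):
    model, truth, exps = cascade3
    worse = set_parameter(
        model, ParameterRef("act_1_1.kact"), truth["act_1_1.kact"] * 3
    )
    report = score_model(worse, exps[:2], weights=[1.0, 3.0])
    per = [e["nrms"] for e in report.entries]
    assert report.wnrms == pytest.approx(
        math.sqrt((1 * per[0] ** 2 + 3 * per[1] ** 2) / 4)
    )


def test_score_skips_unknown_entities(cascade3):
    model, _, exps = cascade3
    alien = ExperimentDef(
        id="alien", protocol="timeseries", settle_time=0.0,
        readouts=[ro("NotASpecies", [[1.0, 1.0]])],
    )
    report = score_model(model, list(exps) + [alien])
    assert report.n_skipped == 1
    with pytest.raises(ValueError):
        score_model(model, [alien])


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------

def test_cascade_generator_deterministic():
    m1, t1 = generate_synthetic_cascade(3, 2, seed=9)
    m2, t2 = generate_synthetic_cascade(3, 2, seed=9)
    assert t1 == t2
    assert [r.rate_law for r in m1.reactions] == [r.rate_law for r in m2.reactions]


def test_experiments_noiseless_reproduce_truth(cascade3):
    model, truth, _ = cascade3
    exps = generate_synthetic_experiments(model, truth, noise_sd=0.0, seed=5)
    assert score_model(model, exps).wnrms < 1e-6


def test_experiments_noise_level_calibrated():
    """With sd=0.1 over >=100 points the empirical relative sd is in [0.07, 0.13]."""
    model, truth = generate_synthetic_cascade(3, 3, seed=2)
    times = list(np.linspace(0.25, 8.0, 12))
    templates = [
        {"protocol": "timeseries", "readouts": [s.id], "times": times}
        for s in model.species if s.id.endswith("a")
    ]
    clean = generate_synthetic_experiments(model, truth, templates, noise_sd=0.0, seed=3)
    noisy = generate_synthetic_experiments(model, truth, templates, noise_sd=0.1, seed=3)
    rel = []
    for e0, e1 in zip(clean, noisy):
        y0, y1 = e0.readouts[0].y(), e1.readouts[0].y()
        rel += list((y1 - y0) / y0)
    assert len(rel) >= 100
    assert 0.07 <= float(np.std(rel)) <= 0.13


def test_conflicting_experiments_admit_no_perfect_fit(cascade3):
    """Two shifted copies of the same readout cannot both be fitted."""
    model, truth, exps = cascade3
    a = exps[0]
    shifted = ExperimentDef(
        id="conflict", protocol="timeseries", settle_time=0.0,
        readouts=[ro(a.readouts[0].entity,
                     [[x, y * 1.5] for x, y in zip(a.readouts[0].x(), a.readouts[0].y())])],
    )
    pair = [a, shifted]
    # any parameter vector leaves residual: predictions are common to both
    for factor in (0.5, 1.0, 2.0):
        m = set_parameter(model, ParameterRef("act_1_1.kact"),
                          truth["act_1_1.kact"] * factor)
        assert score_model(m, pair).wnrms > 0.05
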