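"""Vector fields, simulation, positivity, and saturation bounds."""

import numpy as np
import pytest

import robnet as rn
from robnet.io import model_from_dict


def test_unit_srna_field_value(unit_srna):
    _, _, f = unit_srna
    assert np.allclose(f(0.0, np.array([1.0, 1.0])), [-1.0, -1.0])


def test_field_vanishes_at_origin_without_production(srna_model):
    cfg = rn.SamplingConfig(term_params={
        "c1": {"value": 0.0}, "c2": {"value": 0.0},
        "b11": {"value": 1.0}, "b22": {"value": 1.0},
        "b12": {"slope": 1.0}})
    # zero production needs the nonnegative-constant tag
    from dataclasses import replace
    from robnet.tags import PropertyTag
    terms = tuple(replace(t, tag=PropertyTag.NONNEGATIVE_CONSTANT)
                  if t.name in ("c1", "c2") else t for t in srna_model.terms)
    model = rn.NetworkModel(state_names=srna_model.state_names,
                            terms=terms, name="srna0")
    inst = rn.sample_instance(model, cfg, seed=0)
    f = rn.assemble_rhs(model, inst)
    assert np.allclose(f(0.0, np.zeros(2)), 0.0)


def test_missing_input_binding_raises():
    model = rn.load_packaged_model("arabinose")
    inst = rn.sample_instance(model, seed=0, verify=False)
    with pytest.raises(ValueError, match="not bound"):
        rn.assemble_rhs(model, inst, {})


def test_toy_model_large_x1_kills_decreasing_production():
    """With the repressor saturated high, the repressed RNA sees only its
    degradation: dx2/dt ~ -(b22 + b2u*u2) x2."""
    from test_model import toy_repression_model
    model = toy_repression_model()
    cfg = rn.SamplingConfig(term_params={
        "a1u1": {"value": 1.0}, "b11": {"value": 1.0},
        "d21": {"amplitude": 1.0, "K": 1.0, "H": 2.0},
        "b22": {"value": 0.7}, "b2u2": {"slope": 0.3},
        "a32": {"value": 1.0}, "b33": {"value": 1.0}})
    inst = rn.sample_instance(model, cfg, seed=0)
    f = rn.assemble_rhs(model, inst, {"u1": 1.0, "u2": 2.0})
    x = np.array([1e6, 3.0, 1.0])
    expected = -(0.7 + 0.3 * 2.0) * 3.0
    assert f(0.0, x)[1] == pytest.approx(expected, rel=1e-6)


def test_batch_evaluation_matches_pointwise(unit_srna):
    _, _, f = unit_srna
    X = np.random.default_rng(0).uniform(0, 3, size=(40, 2))
    B = f.eval_batch(X)
    for x, b in zip(X, B):
        assert np.allclose(f(0.0, x), b, atol=1e-12)


def test_simulation_from_equilibrium_stays(unit_srna):
    _, _, f = unit_srna
    xs = np.array([(np.sqrt(5) - 1) / 2] * 2)
    traj = rn.simulate(f, xs, (0.0, 20.0))
    assert np.max(np.abs(traj.states - xs)) < 1e-8


def test_trajectories_componentwise_nonnegative(unit_srna):
    _, _, f = unit_srna
    traj = rn.simulate(f, [5.0, 5.0], (0.0, 50.0))
    assert traj.states.min() >= 0.0
    assert np.all(np.diff(traj.times) > 0)


def test_negative_initial_condition_rejected(unit_srna):
    _, _, f = unit_srna
    with pytest.raises(ValueError):
        rn.simulate(f, [-0.1, 1.0], (0.0, 1.0))


def test_steady_flagging(unit_srna):
    _, _, f = unit_srna
    traj = rn.simulate(f, [5.0, 5.0], (0.0, 5.0), until_steady=True)
    assert traj.steady
    assert f.is_steady(traj.final)


def test_invariant_box_srna_sum_bound_is_two(unit_srna):
    model, inst, _ = unit_srna
    box = rn.invariant_box(model, inst)
    assert box.sum_bound == pytest.approx(2.0)
    assert np.allclose(box.upper, [1.0, 1.0])


def test_invariant_box_arabinose_cascade_is_finite(cases):
    case = cases("arabinose")
    box = rn.invariant_box(case.model, case.default_instance, {"u": 1.0})
    assert np.all(np.isfinite(box.upper))


def test_unbounded_production_without_degradation_gives_inf():
    model = model_from_dict({
        "name": "blowup", "states": ["x1", "x2"], "inputs": [],
        "terms": [
            {"name": "c1", "target": "x1", "kind": "c", "arg": "x2",
             "tag": "increasing-asymptotically-unbounded"},
            {"name": "b11", "target": "x1", "kind": "b", "mult": "x1",
             "tag": "positive-constant"},
            {"name": "c2", "target": "x2", "kind": "c",
             "tag": "positive-constant"},
        ]})
    inst = rn.sample_instance(model, seed=0, verify=False)
    box = rn.invariant_box(model, inst)
    assert not np.isfinite(box.upper[1])
    assert not np.isfinite(box.upper[0])
    assert not np.isfinite(box.sum_bound)


def test_sum_bound_never_exceeded(unit_srna):
    model, inst, f = unit_srna
    box = rn.invariant_box(model, inst)
    rng = np.random.default_rng(4)
    for _ in range(5):
        x0 = rng.uniform(0, 3, size=2)
        traj = rn.simulate(f, x0, (0.0, 30.0))
        sums = traj.states.sum(axis=1)
        assert np.max(sums) <= max(x0.sum(), box.sum_bound) + 1e-7


def test_conserved_pools_drift_below_1e6_relative(cases):
    case = cases("mapk")
    f = rn.assemble_rhs(case.extras["full_model"],
                        case.extras["full_instance"])
    rng = np.random.default_rng(8)
    x0 = rng.uniform(0.1, 1.0, size=7)
    traj = rn.simulate(f, x0, (0.0, 80.0))
    for w in [(0, 1, 1, 1, 0, 0, 0), (0, 0, 0, 0, 1, 1, 1)]:
        series = traj.states @ np.asarray(w, float)
        assert np.max(np.abs(series - series[0])) / series[0] < 1e-6


def test_trajectory_csv_roundtrip(tmp_path, unit_srna):
    model, _, f = unit_srna
    traj = rn.simulate(f, [1.0, 2.0], (0.0, 5.0))
    path = tmp_path / "traj.csv"
    from robnet.dynamics import trajectory_to_csv
    trajectory_to_csv(traj, model, path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert data.shape == (len(traj.times), 3)
    header = path.read_text().splitlines()[0]
    assert header == "t,x1,x2"
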