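"""Lyapunov, Nagumo, sector certificates; crossings; decay rates."""

import numpy as np
import pytest

import robnet as rn
from robnet.certificates import PiecewiseLinearFunction

GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
XSTAR = np.array([GOLDEN, GOLDEN])


def test_one_norm_value_and_active_set():
    V = PiecewiseLinearFunction.weighted_one_norm(np.array([1.0, 2.0]),
                                                  weights=[2.0, 3.0])
    x = np.array([[1.5, 1.0]])
    assert V.value(x)[0] == pytest.approx(2 * 0.5 + 3 * 1.0)
    # at the center the value is 0 and every piece is active, so the
    # generalized derivative is the weighted 1-norm of the field
    c = np.array([[1.0, 2.0]])
    assert V.value(c)[0] == 0.0
    D = V.directional_derivative(c, np.array([[0.5, -0.25]]))
    assert D[0] == pytest.approx(2 * 0.5 + 3 * 0.25)


def test_one_norm_positive_definite(unit_srna):
    V = PiecewiseLinearFunction.weighted_one_norm(XSTAR)
    X = np.random.default_rng(0).uniform(0, 2, size=(200, 2))
    assert V.positive_definite_on(X)


def test_decrease_certificate_holds_with_rate_at_least_min_turnover(unit_srna):
    _, _, f = unit_srna
    V = PiecewiseLinearFunction.weighted_one_norm(XSTAR)
    rep = rn.decrease_certificate(f, V, np.array([2.0, 2.0]),
                                  n_samples=20000, seed=1)
    assert rep.holds
    assert rep.estimated_rate >= 1.0 - 1e-9  # min(b11, b22) = 1


def test_reversed_field_fails_decrease(unit_srna):
    _, _, f = unit_srna

    class Neg:
        dimension = 2
        def __call__(self, t, x):
            return -f(t, x)
        def eval_batch(self, X, t=0.0):
            return -f.eval_batch(X, t)

    V = PiecewiseLinearFunction.weighted_one_norm(XSTAR)
    rep = rn.decrease_certificate(Neg(), V, np.array([2.0, 2.0]),
                                  n_samples=4000, seed=1)
    assert not rep.holds and rep.worst_margin > 0
    assert len(rep.witnesses) == 1


def test_decrease_requires_equilibrium_center(unit_srna):
    _, _, f = unit_srna
    V = PiecewiseLinearFunction.weighted_one_norm(np.array([1.5, 1.5]))
    with pytest.raises(ValueError, match="not an equilibrium"):
        rn.decrease_certificate(f, V, np.array([2.0, 2.0]), n_samples=100)


def test_nagumo_sum_trap_holds_and_boundary_arithmetic(unit_srna):
    _, _, f = unit_srna
    cs = rn.ConstraintSet([
        rn.LinearConstraint(np.array([1.0, 1.0]), 2.0, "x1+x2<=2"),
        rn.LinearConstraint(np.array([-1.0, 0.0]), 0.0, "x1>=0"),
        rn.LinearConstraint(np.array([0.0, -1.0]), 0.0, "x2>=0"),
    ])
    rep = rn.nagumo_certificate(f, cs, np.array([2.0, 2.0]),
                                n_boundary=800, seed=2)
    assert rep.holds
    # hand value at the boundary point (1,1): c1+c2-b11-b22-2k = -2
    sdot = float(np.dot([1.0, 1.0], f(0.0, np.array([1.0, 1.0]))))
    assert sdot == pytest.approx(-2.0)


def test_nagumo_detects_escapable_set(unit_srna):
    _, _, f = unit_srna
    cs = rn.ConstraintSet([
        rn.LinearConstraint(np.array([1.0, 0.0]), GOLDEN / 2, "x1 small")])
    rep = rn.nagumo_certificate(f, cs, np.array([2.0, 2.0]),
                                n_boundary=400, seed=2)
    assert not rep.holds and rep.worst_margin > 0


def test_nagumo_function_constraint_matches_linear(unit_srna):
    _, _, f = unit_srna
    lin = rn.ConstraintSet([
        rn.LinearConstraint(np.array([1.0, 1.0]), 2.0)])
    fun = rn.ConstraintSet([
        rn.FunctionConstraint(lambda x: x[0] + x[1], 2.0)])
    r1 = rn.nagumo_certificate(f, lin, np.array([2.0, 2.0]),
                               n_boundary=300, seed=3)
    r2 = rn.nagumo_certificate(f, fun, np.array([2.0, 2.0]),
                               n_boundary=300, seed=3)
    assert r1.holds == r2.holds
    assert r1.worst_margin == pytest.approx(r2.worst_margin, rel=1e-3)


def test_certificate_monotone_in_sampling_density(unit_srna):
    """More samples can only degrade the reported margin (Halton points
    form a prefix sequence), so a failing certificate never flips to
    passing."""
    _, _, f = unit_srna
    cs = rn.ConstraintSet([
        rn.LinearConstraint(np.array([1.0, 0.0]), GOLDEN / 2)])
    margins = [rn.nagumo_certificate(f, cs, np.array([2.0, 2.0]),
                                     n_boundary=n, seed=7).worst_margin
               for n in (200, 800, 3200)]
    assert margins[0] <= margins[1] + 1e-12 <= margins[2] + 2e-12

    V = PiecewiseLinearFunction.weighted_one_norm(XSTAR)
    worst = [rn.decrease_certificate(f, V, np.array([2.0, 2.0]),
                                     n_samples=n, seed=7).worst_margin
             for n in (1000, 4000, 16000)]
    assert worst[0] <= worst[1] + 1e-12 <= worst[2] + 2e-12


def test_sector_invariance_and_its_violation(unit_srna):
    _, _, f = unit_srna
    good = rn.sector_certificate(f, XSTAR, (">=", "<="),
                                 np.array([2.0, 2.0]), n_boundary=800, seed=4)
    bad = rn.sector_certificate(f, XSTAR, (">=", ">="),
                                np.array([2.0, 2.0]), n_boundary=800, seed=4)
    assert good.holds and not bad.holds


def test_crossing_counts(unit_srna):
    _, _, f = unit_srna
    traj = rn.simulate(f, XSTAR, (0.0, 10.0))
    assert np.all(rn.crossing_count(traj, XSTAR) == 0)
    traj = rn.simulate(f, [5.0, 0.0], (0.0, 60.0), until_steady=True)
    assert np.all(rn.crossing_count(traj, XSTAR) <= 1)


def test_decay_rate_fits_exponential():
    t = np.linspace(0, 20, 400)
    rate, warn = rn.decay_rate(t, 3.0 * np.exp(-0.7 * t))
    assert rate == pytest.approx(0.7, rel=1e-6)
    assert warn == ""


def test_decay_rate_constant_series_is_zero():
    t = np.linspace(0, 5, 50)
    rate, _ = rn.decay_rate(t, np.ones_like(t))
    assert rate == 0.0


def test_decay_rate_warns_on_nonmonotone():
    t = np.linspace(0, 10, 200)
    V = np.exp(-t) * (1.0 + 0.2 * np.sin(8 * t))
    _, warn = rn.decay_rate(t, V)
    assert "monoton" in warn


def test_simulated_decay_meets_certificate_rate(unit_srna):
    _, _, f = unit_srna
    V = PiecewiseLinearFunction.weighted_one_norm(XSTAR)
    cert = rn.decrease_certificate(f, V, np.array([2.0, 2.0]),
                                   n_samples=8000, seed=5)
    traj = rn.simulate(f, [1.8, 0.3], (0.0, 60.0), until_steady=True)
    rate, _ = rn.decay_rate(traj.times, V.value(traj.states))
    assert rate >= 0.9 * cert.estimated_rate


def test_nagumo_passing_sets_are_never_exited(unit_srna):
    """Soundness against simulation for the sum trap."""
    _, _, f = unit_srna
    rng = np.random.default_rng(11)
    for _ in range(20):
        x0 = rng.uniform(0, 1, size=2)
        x0 = x0 / max(x0.sum(), 1.0) * rng.uniform(0, 2.0)
        traj = rn.simulate(f, x0, (0.0, 30.0))
        assert np.max(traj.states.sum(axis=1)) <= 2.0 + 1e-7
        assert traj.states.min() >= 0.0
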