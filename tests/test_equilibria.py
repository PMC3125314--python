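"""Root finding, classification, ordering, response curves."""

import numpy as np
import robnet as rn
from robnet.equilibria import Equilibrium, check_order, jacobian_fd

GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def test_unit_srna_equilibrium_matches_closed_form(unit_srna):
    _, _, f = unit_srna
    eqs = rn.find_equilibria(f, [2.0, 2.0], n_starts=100, seed=0)
    assert len(eqs) == 1
    assert np.max(np.abs(eqs[0].state - GOLDEN)) < 1e-8


def test_unit_srna_eigenvalues_match_analytic(unit_srna):
    _, _, f = unit_srna
    eqs = rn.find_equilibria(f, [2.0, 2.0], n_starts=60, seed=0)
    eig = np.sort(np.real(eqs[0].eigenvalues))
    # analytic 2x2 Jacobian [[-1-kx*, -kx*], [-kx*, -1-kx*]]:
    # eigenvalues -1 and -1-2x* = -sqrt(5)
    assert np.allclose(eig, [-np.sqrt(5.0), -1.0], atol=1e-6)
    assert eqs[0].stable


def test_multistart_matches_dense_grid_bisection_oracle(cases):
    """On the 2-state annihilation module the root set from multistart
    equals a nullcline sign-change/bisection scan."""
    from scipy.optimize import brentq
    inst = cases("srna").sample(np.random.SeedSequence(123))
    f = rn.assemble_rhs(inst.model, inst)
    kappa = rn.invariant_box(inst.model, inst).sum_bound

    # oracle: x2*(x1) from the x2-balance, then scan the x1-residual
    c1 = inst.param("c1", "value"); c2 = inst.param("c2", "value")
    b11 = inst.param("b11", "value"); b22 = inst.param("b22", "value")
    k = inst.param("b12", "slope")

    def x2_of(x1):
        return c2 / (b22 + k * x1)

    def resid(x1):
        return c1 - b11 * x1 - k * x1 * x2_of(x1)

    grid = np.linspace(0.0, kappa, 2000)
    vals = [resid(x) for x in grid]
    roots = []
    for i in range(len(grid) - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]):
            x1 = brentq(resid, grid[i], grid[i + 1], xtol=1e-14)
            roots.append([x1, x2_of(x1)])
    found = rn.find_equilibria(f, [kappa, kappa], n_starts=150, seed=5)
    assert len(found) == len(roots) == 1
    assert np.max(np.abs(found[0].state - roots[0])) < 1e-7


def test_classify_linear_decay():
    class Lin:
        dimension = 1
        def __call__(self, t, x):
            return -np.asarray(x)
        def eval_batch(self, X, t=0.0):
            return -np.atleast_2d(X)
    eq = rn.classify(Lin(), np.zeros(1))
    assert eq.classification == "stable"
    assert np.allclose(eq.eigenvalues, [-1.0], atol=1e-7)


def test_classification_agrees_with_perturbed_simulation(cases):
    """Stable means return, unstable means departure, for 1e-3-scale
    perturbations on the lac bistable point."""
    case = cases("lac")
    u = case.extras["u_bistable"]
    f = rn.assemble_rhs(case.model, case.default_instance, {"u": u})
    from robnet.cases.lac import search_box
    eqs = rn.find_equilibria(f, search_box(case.default_instance, u),
                             n_starts=200, seed=0)
    assert [e.classification for e in eqs] == ["stable", "unstable", "stable"]
    for eq in eqs:
        scale = 1e-3 * (1.0 + np.max(np.abs(eq.state)))
        x0 = np.clip(eq.state + scale, 0.0, None)
        traj = rn.simulate(f, x0, (0.0, 200.0))
        dist = np.max(np.abs(traj.final - eq.state))
        if eq.stable:
            assert dist < scale
        else:
            assert dist > 10 * scale


def test_residuals_below_tolerance(cases):
    inst = cases("srna").default_instance
    f = rn.assemble_rhs(inst.model, inst)
    for eq in rn.find_equilibria(f, [2.0, 2.0], n_starts=50, seed=2):
        assert eq.residual < 1e-9 * (1.0 + np.max(np.abs(eq.state)))


def test_check_order_total_and_degenerate():
    a = Equilibrium(state=np.array([0.1, 0.2]), residual=0.0)
    b = Equilibrium(state=np.array([0.5, 0.6]), residual=0.0)
    ordered, perm = check_order([b, a])
    assert ordered and perm == (1, 0)
    ordered, perm = check_order([a, a])
    assert ordered
    c = Equilibrium(state=np.array([0.6, 0.1]), residual=0.0)
    ordered, _ = check_order([a, c])
    assert not ordered


def test_check_order_with_reversed_block():
    a = Equilibrium(state=np.array([0.1, 0.9]), residual=0.0)
    b = Equilibrium(state=np.array([0.5, 0.3]), residual=0.0)
    ordered, _ = check_order([a, b])
    assert not ordered
    ordered, _ = check_order([a, b], directions={1: -1})
    assert ordered


def test_jacobian_fd_on_known_quadratic(unit_srna):
    _, _, f = unit_srna
    x = np.array([GOLDEN, GOLDEN])
    J = jacobian_fd(f, x)
    expected = np.array([[-1 - GOLDEN, -GOLDEN], [-GOLDEN, -1 - GOLDEN]])
    assert np.max(np.abs(J - expected)) < 1e-6


def test_response_curve_branch_counts_lac(cases):
    case = cases("lac")
    grid = np.geomspace(0.5, 12.0, 6)
    rc = rn.response_curve(case.model, case.default_instance, "u", grid,
                           n_starts=120, seed=0)
    counts = rc.counts()
    assert counts[0] == 1 and counts[-1] == 3 or 3 in counts
    assert rc.folds  # the count changes somewhere along the grid


def test_response_curve_monotone_srna_in_c2(cases):
    """Steady states are decreasing (x1) and increasing (x2) in the sRNA
    transcription rate c2, read off closed-form balance across stepped
    instances."""
    inst = cases("srna").default_instance
    vals = []
    for c2 in np.geomspace(0.5, 8.0, 6):
        stepped = inst.with_param("c2", value=c2)
        f = rn.assemble_rhs(stepped.model, stepped)
        eqs = rn.find_equilibria(f, [20.0, 20.0], n_starts=60, seed=1)
        assert len(eqs) == 1
        vals.append(eqs[0].state)
    vals = np.stack(vals)
    assert np.all(np.diff(vals[:, 0]) < 0)
    assert np.all(np.diff(vals[:, 1]) > 0)
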