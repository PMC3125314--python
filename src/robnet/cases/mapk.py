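"""MAPK cascade case study.

Reduced coordinates (x1, x2, x4, x5, x7): the conserved pools
x2+x3+x4 = k and x5+x6+x7 = h eliminate the mono-phosphorylated forms.
The interior tiers are monotone input-output stages, so for a held MAP3K
level x1 the cascade equilibrium is unique and the whole equilibrium set
is the root set of one scalar residual

    Phi(x1) = c10 + mu * a17(x1) * x7*(x1) - b11(x1) x1

with x7*(x1) the steady doubly-phosphorylated MAPK.  The feedback family
controls the count parity: Phi(0) = c10 > 0, so a feedback whose
coefficient grows unboundedly in x1 forces Phi(+inf) = +inf and an even
number of equilibria (typically 0 or 2), while bounded feedback at
moderate gain admits odd runs (1 or 3, alternately stable / unstable);
a positively lower-bounded coefficient at large gain mu removes all
equilibria.  Without feedback (mu = 0) the cascade has a unique globally
stable equilibrium, provided c10 stays below the MAP3K turnover ceiling.

The scalar residual doubles as the dense-grid oracle that sizes the
multistart search box.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import brentq

from ..dynamics import assemble_rhs, simulate
from ..ensemble import ConcreteInstance, SamplingConfig, sample_instance
from ..equilibria import check_order, find_equilibria
from ..functions import make_function
from ..model import NetworkModel, detect_conserved_sums
from ..tags import PropertyTag
from .base import CaseStudy, Claim, ClaimResult, frozen_config, load, register_case

#: frozen default kinetics: ultrasensitive tiers (half-saturations well
#: below the conserved totals), MAP3K turnover ceiling 1, basal input 0.05
_E = {"amplitude": 1.0, "K": 0.05}     # phosphorylation coefficient per kinase
_G = {"amplitude": 0.25, "K": 0.05}    # dephosphorylation flux
DEFAULT_PARAMS = {
    "c10": {"value": 0.05},
    "a17": {"value": 0.3},             # constant feedback, bistable gain
    "b11": {"amplitude": 1.0, "K": 1.0},
    "c23": dict(_G), "b21": dict(_E), "a41": dict(_E), "b44": dict(_G),
    "c56": dict(_G), "b54": dict(_E), "a74": dict(_E), "b77": dict(_G),
    # full-coordinate aliases: the first term of each coupling group is the
    # one the sampler draws, so every member name is pinned identically
    "a31": dict(_E), "b31": dict(_E), "b33": dict(_G), "c34": dict(_G),
    "a64": dict(_E), "b64": dict(_E), "b66": dict(_G), "c67": dict(_G),
}
DEFAULT_CONSTANTS = {"k": 1.0, "h": 1.0}

FEEDBACK_FAMILIES = {
    "constant": ("constant", "value", PropertyTag.NONNEGATIVE_CONSTANT),
    "bounded_increasing": ("mm_saturating", "amplitude",
                           PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT),
    "unbounded_increasing": ("linear_unbounded", "slope",
                             PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED),
}

MU_GRID_CONSTANT = (0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0, 3.0)
MU_GRID_LINEAR = tuple(np.geomspace(0.01, 100.0, 9))
MU_LARGE = 1e6


def with_feedback(instance: ConcreteInstance, family: str, mu: float,
                  K: float = 0.5) -> ConcreteInstance:
    """Swap the a17 feedback term to the given qualitative family at gain
    ``mu`` (model tag updated alongside the assignment)."""
    fam, gain_name, tag = FEEDBACK_FAMILIES[family]
    params = {gain_name: mu} if mu > 0 else {gain_name: mu}
    if fam == "mm_saturating":
        params["K"] = K
    if fam == "constant":
        fn = make_function("constant", {"value": mu},
                           PropertyTag.NONNEGATIVE_CONSTANT)
    elif mu == 0:
        fn = make_function("constant", {"value": 0.0},
                           PropertyTag.NONNEGATIVE_CONSTANT)
        tag = PropertyTag.NONNEGATIVE_CONSTANT
    else:
        fn = make_function(fam, params, tag)
    model = instance.model
    terms = tuple(replace(t, tag=fn.claimed_tag, family=fn.family_id)
                  if t.name == "a17" else t for t in model.terms)
    new_model = NetworkModel(state_names=model.state_names,
                             input_names=model.input_names, terms=terms,
                             notes=model.notes, name=model.name)
    assigns = dict(instance.assignments)
    assigns["a17"] = fn
    return ConcreteInstance(model=new_model, assignments=assigns,
                            modulator_assignments=dict(instance.modulator_assignments),
                            constants=dict(instance.constants),
                            seed=instance.seed)


# ---------------------------------------------------------------------------
# scalar reduction
# ---------------------------------------------------------------------------

def _inv(phi, y: float, hi0: float) -> float:
    """Inverse of an increasing scalar function with saturation; returns a
    huge sentinel when y is at or above the saturation level."""
    if y <= 0:
        return 0.0
    hi = hi0
    while phi(hi) < y:
        hi *= 2.0
        if hi > 1e12 * hi0:
            return np.inf
    return brentq(lambda x: phi(x) - y, 0.0, hi, xtol=1e-15, rtol=8.9e-16)


def _stage_eq(w: float, T: float, e_a, e_b, g_a, g_b, scale: float):
    """Equilibrium (s0, s1, s2) of one dual-(de)phosphorylation tier with
    kinase level w: w*e_a(s0) = g_a(s1) and w*e_b(s1) = g_b(s2) on the
    simplex s0+s1+s2 = T.  The total filled by the three forms is
    increasing in s1, so a single bisection resolves the tier."""
    if w <= 0 or T <= 0:
        return (T, 0.0, 0.0)

    def filled(s1):
        s0 = _inv(e_a, g_a(s1) / w, scale)
        s2 = _inv(g_b, w * e_b(s1), scale)
        return s0 + s1 + s2

    if filled(0.0) >= T:
        return (T, 0.0, 0.0)
    lo, hi = 0.0, T
    while filled(hi) < T:  # pragma: no cover - defensive
        hi *= 1.5
    s1 = brentq(lambda s: filled(s) - T, lo, hi, xtol=1e-14, rtol=8.9e-16)
    s0 = _inv(e_a, g_a(s1) / w, scale)
    s2 = max(T - s0 - s1, 0.0)
    return (s0, s1, s2)


def cascade_output(instance: ConcreteInstance, x1: float):
    """(x4*, x7*) for a held MAP3K level x1."""
    k = instance.constants["k"]
    h = instance.constants["h"]
    sc = instance.fn("b21").scale
    e1 = instance.fn("b21").as_scalar()
    e2 = instance.fn("a41").as_scalar()
    g1 = instance.fn("c23").as_scalar()
    g2 = instance.fn("b44").as_scalar()
    _, _, x4 = _stage_eq(x1, k, e1, e2, g1, g2, sc)
    e3 = instance.fn("b54").as_scalar()
    e4 = instance.fn("a74").as_scalar()
    g3 = instance.fn("c56").as_scalar()
    g4 = instance.fn("b77").as_scalar()
    _, _, x7 = _stage_eq(x4, h, e3, e4, g3, g4, sc)
    return x4, x7


def cascade_state(instance: ConcreteInstance, x1: float) -> np.ndarray:
    """Full reduced state (x1, x2, x4, x5, x7) with both tiers at their
    unique equilibrium for a held x1."""
    k = instance.constants["k"]
    h = instance.constants["h"]
    sc = instance.fn("b21").scale
    s0, _, x4 = _stage_eq(x1, k, instance.fn("b21").as_scalar(),
                          instance.fn("a41").as_scalar(),
                          instance.fn("c23").as_scalar(),
                          instance.fn("b44").as_scalar(), sc)
    s5, _, x7 = _stage_eq(x4, h, instance.fn("b54").as_scalar(),
                          instance.fn("a74").as_scalar(),
                          instance.fn("c56").as_scalar(),
                          instance.fn("b77").as_scalar(), sc)
    return np.array([x1, s0, x4, s5, x7])


def scalar_residual(instance: ConcreteInstance, x1_grid) -> np.ndarray:
    c10 = instance.param("c10", "value")
    a17 = instance.fn("a17").as_scalar()
    g11 = instance.fn("b11").as_scalar()
    out = np.empty(len(x1_grid))
    for i, x1 in enumerate(x1_grid):
        _, x7 = cascade_output(instance, x1)
        out[i] = c10 + a17(x1) * x7 - g11(x1)
    return out


def scalar_equilibria(instance: ConcreteInstance, n_grid: int = 160,
                      x1_max: float | None = None) -> np.ndarray:
    """Dense-grid sign-change estimate of the equilibrium MAP3K levels."""
    K1 = instance.fn("b11").scale
    if x1_max is None:
        x1_max = 1e3 * K1
    grid = np.concatenate([[0.0], np.geomspace(1e-5 * K1, x1_max, n_grid)])
    r = scalar_residual(instance, grid)
    roots = []
    for i in np.nonzero(np.diff(np.sign(r)) != 0)[0]:
        roots.append(brentq(
            lambda x: scalar_residual(instance, [x])[0],
            grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16))
    return np.asarray(roots)


def search_box(instance: ConcreteInstance,
               roots: np.ndarray | None = None) -> np.ndarray:
    k = instance.constants["k"]
    h = instance.constants["h"]
    K1 = instance.fn("b11").scale
    if roots is None:
        roots = scalar_equilibria(instance)
    x1cap = 3.0 * float(np.max(roots)) + K1 if roots.size else 20.0 * K1
    return np.array([x1cap, k, k, h, h])


# ---------------------------------------------------------------------------
# scans and claims
# ---------------------------------------------------------------------------

def equilibria_for(var: ConcreteInstance, n_starts: int = 200, seed: int = 0):
    """Multistart equilibria of a concrete (feedback-resolved) instance,
    with informed starts from the scalar reduction."""
    f = assemble_rhs(var.model, var)
    roots = scalar_equilibria(var)
    informed = [cascade_state(var, x1) for x1 in roots]
    return find_equilibria(f, search_box(var, roots), n_starts=n_starts,
                           seed=seed, extra_starts=informed)


def mapk_scan(instance: ConcreteInstance, mu_grid, feedback_family: str,
              n_starts: int = 80, seed: int = 0):
    """Equilibrium count and stability per feedback gain."""
    out = []
    for j, mu in enumerate(mu_grid):
        var = with_feedback(instance, feedback_family, float(mu))
        f = assemble_rhs(var.model, var)
        roots = scalar_equilibria(var)
        informed = [cascade_state(var, x1) for x1 in roots]
        eqs = find_equilibria(f, search_box(var, roots), n_starts=n_starts,
                              seed=seed + j, extra_starts=informed)
        out.append({"mu": float(mu), "count": len(eqs),
                    "classes": [e.classification for e in eqs],
                    "x1": [float(e.state[0]) for e in eqs]})
    return out


def claim_mu0_unique_stable(case, instance, seed) -> ClaimResult:
    var = with_feedback(instance, "constant", 0.0)
    eqs = equilibria_for(var, n_starts=200, seed=seed)
    holds = len(eqs) == 1 and eqs[0].stable
    return ClaimResult("mu0_unique_stable", holds,
                       {"count": len(eqs),
                        "classes": [e.classification for e in eqs]})


def claim_conservation(case, instance, seed) -> ClaimResult:
    """Full-coordinate model: the two pool sums are detected and drift less
    than 1e-6 relative along simulations from random states."""
    full_model = case.extras["full_model"]
    full_inst = case.extras["full_instance"]
    sums = detect_conserved_sums(full_model, full_inst, seed=seed)
    weights = sorted(tuple(s.weights) for s in sums)
    expected = [(0, 0, 0, 0, 1, 1, 1), (0, 1, 1, 1, 0, 0, 0)]
    f = assemble_rhs(full_model, full_inst)
    rng = np.random.default_rng(seed)
    drift_ok = True
    worst = 0.0
    for _ in range(3):
        x0 = rng.uniform(0.05, 1.0, size=7)
        traj = simulate(f, x0, (0.0, 50.0))
        for w in expected:
            series = traj.states @ np.asarray(w, dtype=float)
            rel = float(np.max(np.abs(series - series[0])) / series[0])
            worst = max(worst, rel)
            drift_ok &= rel < 1e-6
    return ClaimResult("conservation", weights == expected and drift_ok,
                       {"weights": weights, "worst_drift": worst})


def claim_bistable_window(case, instance, seed) -> ClaimResult:
    scan = mapk_scan(instance, MU_GRID_CONSTANT, "constant", seed=seed)
    three = [s for s in scan if s["count"] == 3]
    sus = all(s["classes"] == ["stable", "unstable", "stable"] for s in three)
    order_ok = True
    for s in three:
        var = with_feedback(instance, "constant", s["mu"])
        eqs = equilibria_for(var, n_starts=120, seed=seed)
        ordered, _ = check_order(eqs, subset=[0, 2, 4])
        rev_ordered, _ = check_order(eqs, subset=[0, 1, 3],
                                     directions={1: -1, 3: -1})
        order_ok &= ordered and rev_ordered
    return ClaimResult("bistable_window", bool(three) and sus and order_ok,
                       {"counts": [s["count"] for s in scan],
                        "n_three": len(three)})


def claim_no_equilibria_large_mu(case, instance, seed) -> ClaimResult:
    var = with_feedback(instance, "constant", MU_LARGE)
    eqs = equilibria_for(var, n_starts=120, seed=seed)
    oracle = scalar_equilibria(var)
    return ClaimResult("no_equilibria_large_mu",
                       len(eqs) == 0 and oracle.size == 0,
                       {"count": len(eqs)})


def claim_even_counts_linear(case, instance, seed) -> ClaimResult:
    scan = mapk_scan(instance, MU_GRID_LINEAR, "unbounded_increasing",
                     seed=seed)
    counts = [s["count"] for s in scan]
    even = all(c % 2 == 0 for c in counts)
    pair_ok = all(s["classes"] in (["stable", "unstable"],
                                   ["unstable", "stable"])
                  for s in scan if s["count"] == 2)
    some = any(c == 2 for c in counts)
    return ClaimResult("even_counts_linear", even and pair_ok and some,
                       {"counts": counts})


@register_case("mapk")
def build() -> CaseStudy:
    model = load("mapk")
    full_model = load("mapk_full")
    inst = sample_instance(model, frozen_config(DEFAULT_PARAMS,
                                                constants=DEFAULT_CONSTANTS),
                           seed=0)
    full_inst = sample_instance(full_model, frozen_config(DEFAULT_PARAMS),
                                seed=0)
    cfg = SamplingConfig(
        term_params={
            "c10": {"value": (0.01, 0.2)},
            "a17": {"value": 0.0},
            "b11": {"amplitude": (0.5, 2.0), "K": (0.2, 2.0)},
            **{t: {"amplitude": (0.3, 3.0), "K": (0.02, 0.5)}
               for t in ("b21", "a41", "b54", "a74")},
            **{t: {"amplitude": (0.05, 0.5), "K": (0.02, 0.5)}
               for t in ("c23", "b44", "c56", "b77")},
        },
        constants={"k": (0.5, 2.0), "h": (0.5, 2.0)})
    claims = [
        Claim("conservation", "pool sums x2+x3+x4 and x5+x6+x7 are detected "
              "and conserved to 1e-6 relative", claim_conservation,
              scope="default"),
        Claim("mu0_unique_stable", "without feedback the cascade has one "
              "stable equilibrium", claim_mu0_unique_stable),
        Claim("bistable_window", "constant feedback: a gain window with "
              "three equilibria, stable/unstable/stable, partially ordered",
              claim_bistable_window, scope="default"),
        Claim("no_equilibria_large_mu", "lower-bounded feedback at large "
              "gain removes all equilibria", claim_no_equilibria_large_mu,
              scope="default"),
        Claim("even_counts_linear", "unbounded increasing feedback: even "
              "equilibrium counts (0 or 2), stable/unstable pairs",
              claim_even_counts_linear, scope="default"),
    ]
    return CaseStudy(name="mapk", model=model, default_instance=inst,
                     sampling_config=cfg, claims=claims,
                     extras={"full_model": full_model,
                             "full_instance": full_inst,
                             "k": DEFAULT_CONSTANTS["k"],
                             "h": DEFAULT_CONSTANTS["h"],
                             "existence_condition":
                                 "c10 < sup_x b11(x) x (MAP3K turnover "
                                 "ceiling)"})
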