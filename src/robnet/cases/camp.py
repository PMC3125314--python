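"""cAMP/PKA signaling case study.

Active G protein x1 relaxes to a glucose-determined level xi(u) (unique
because activation shuts off exactly at the total amount G_tot while
deactivation is linear).  cAMP (x3) is produced at a PKA-inhibited rate
d32(x2) + a31(x2)*x1 and degraded along two phosphodiesterase routes,
b32(x3)*x2 and the saturating flux g33(x3).

Because production is decreasing and degradation increasing in x3 along
the steady-state relation, an equilibrium exists iff the residual is
negative at large x3:

    d32(th2) + a31(th2) * xi(u)  <  b32(inf) * th2 + g33(inf)

(th2 = PKA_tot, the upper saturation of x2); it is then unique, locally
stable, and increasing in u.  When the saturating route alone dominates
worst-case production,

    g33(inf) > p(u),   p(u) = d32(0) + a31(0) * xi(u)       (dominance)

the level set {x3 <= B} with B = g33^{-1}(p(u)) is invariant by the
Nagumo argument, giving the transient bound
x3(t) <= max(x3(0), B) for trajectories started at x1(0) = xi(u).
Without the dominance condition no such bound holds: the cAMP spike is
limited only by PKA catching up and can exceed any such level.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from ..dynamics import assemble_rhs, simulate
from ..ensemble import SamplingConfig, sample_instance
from ..equilibria import find_equilibria
from .base import CaseStudy, Claim, ClaimResult, frozen_config, load, register_case

DEFAULT_PARAMS = {
    "a1u": {"slope": 1.0, "theta": 2.0},
    "b11": {"value": 1.0},
    "a23": {"slope": 1.0, "theta": 2.0},
    "b22": {"value": 1.0},
    "d32": {"amplitude": 0.5, "K": 1.0},
    "a31": {"amplitude": 1.0, "K": 1.0},
    "b32": {"amplitude": 1.0, "K": 1.0},
    "b33": {"amplitude": 3.0, "K": 1.0},
}

#: packaged instance violating the dominance condition: weak saturating
#: phosphodiesterase ceiling, slow PKA activation, fast-decaying
#: PKA inhibition of production -- an equilibrium still exists, but the
#: cAMP spike blows through the level a compliant instance is bounded by
SPIKE_PARAMS = {
    **DEFAULT_PARAMS,
    "a23": {"slope": 0.005, "theta": 2.0},
    "d32": {"amplitude": 0.5, "K": 0.2},
    "a31": {"amplitude": 1.0, "K": 0.2},
    "b32": {"amplitude": 0.05, "K": 1.0},
    "b33": {"amplitude": 0.3, "K": 1.0},
}

DEFAULT_U = 2.0
U_GRID = tuple(np.geomspace(0.1, 10.0, 7))
_BIG = 1e9


def _sup(phi) -> float:
    """Upper saturation level, probed far beyond the characteristic scale."""
    return float(phi(np.asarray([_BIG * phi.scale])).ravel()[0])


def camp_xi(instance, u: float) -> float:
    """Steady active-G-protein level: root of a1u(x1)*u = b11*x1, unique
    and increasing in u, saturating at the a1u threshold."""
    if u < 0:
        raise ValueError("u must be >= 0")
    a1u = instance.fn("a1u").as_scalar()
    b11 = instance.param("b11", "value")
    if u == 0 or a1u(0.0) == 0.0:
        return 0.0
    theta = instance.fn("a1u").scale
    return float(brentq(lambda x: a1u(x) * u - b11 * x, 0.0, theta,
                        xtol=1e-14, rtol=8.9e-16))


def pka_steady(instance, x3: float) -> float:
    """Steady PKA level for a held cAMP level: root of a23(x2)*x3 = b22*x2."""
    a23 = instance.fn("a23").as_scalar()
    b22 = instance.param("b22", "value")
    if x3 <= 0 or a23(0.0) == 0.0:
        return 0.0
    theta = instance.fn("a23").scale
    return float(brentq(lambda x: a23(x) * x3 - b22 * x, 0.0, theta,
                        xtol=1e-14, rtol=8.9e-16))


def _x3_residual(instance, u: float, x3: float) -> float:
    xi = camp_xi(instance, u)
    x2 = pka_steady(instance, x3)
    d32 = instance.fn("d32").as_scalar()
    a31 = instance.fn("a31").as_scalar()
    b32 = instance.fn("b32").as_scalar()
    g33 = instance.fn("b33").as_scalar()
    return d32(x2) + a31(x2) * xi - b32(x3) * x2 - g33(x3)


def camp_existence_check(instance, u: float) -> bool:
    """Equilibrium existence condition: worst-case production at full PKA
    saturation below the total degradation ceiling."""
    xi = camp_xi(instance, u)
    th2 = instance.fn("a23").scale
    d32 = instance.fn("d32").as_scalar()
    a31 = instance.fn("a31").as_scalar()
    lhs = d32(th2) + a31(th2) * xi
    rhs = _sup(instance.fn("b32")) * th2 + _sup(instance.fn("b33"))
    return bool(lhs < rhs)


def camp_equilibrium(instance, u: float) -> np.ndarray | None:
    """Scalar-bracketing equilibrium (the semi-analytic route)."""
    if not camp_existence_check(instance, u):
        return None
    scale = instance.fn("b33").scale
    hi = scale
    r0 = _x3_residual(instance, u, 0.0)
    if r0 <= 0:
        x3 = 0.0
    else:
        while _x3_residual(instance, u, hi) > 0 and hi < 1e12 * scale:
            hi *= 2.0
        x3 = float(brentq(lambda x: _x3_residual(instance, u, x), 0.0, hi,
                          xtol=1e-14, rtol=8.9e-16))
    return np.array([camp_xi(instance, u), pka_steady(instance, x3), x3])


def search_box(instance, u: float) -> np.ndarray:
    """Finite box for multistart root finding: x1, x2 capped just above
    their activation thresholds; x3 capped where the steady-state residual
    has turned negative (or a fixed multiple of the scale when it never
    does and no equilibrium can exist)."""
    th1 = instance.fn("a1u").scale
    th2 = instance.fn("a23").scale
    b11 = instance.param("b11", "value")
    x1cap = max(1.05 * th1, 1.05 * camp_xi(instance, u), 2.0 * th1 * u / max(b11, 1e-12))
    x1cap = min(x1cap, 1.1 * th1)  # activation is exactly null above th1
    scale = instance.fn("b33").scale
    hi = scale
    while _x3_residual(instance, u, hi) > 0 and hi < 1e4 * scale:
        hi *= 2.0
    if _x3_residual(instance, u, hi) > 0:
        # production exceeds the degradation ceiling at every level: no
        # equilibrium exists, a moderate box suffices
        hi = 10.0 * scale
    return np.array([x1cap, 1.05 * th2, 2.0 * hi])


def transient_bound(instance, u: float, x3_0: float = 0.0):
    """Eq-style spike bound ``max(x3(0), g33^{-1}(p(u)))``; ``inf`` when the
    dominance condition fails (the spike is then not structurally bounded
    by the saturating route)."""
    xi = camp_xi(instance, u)
    p = float(instance.fn("d32")(0.0) + instance.fn("a31")(0.0) * xi)
    g33 = instance.fn("b33")
    g_sup = _sup(g33)
    if p >= g_sup:
        return np.inf, p, False
    scale = g33.scale
    hi = scale
    while float(g33(hi)) < p and hi < 1e12 * scale:
        hi *= 2.0
    B = 0.0 if p <= 0 else float(brentq(lambda x: float(g33(x)) - p, 0.0, hi,
                                        xtol=1e-12, rtol=8.9e-16))
    return max(float(x3_0), B), p, True


def camp_transient_bound(instance, u: float, x0, rtol_check: float = 1e-6):
    """Bound value plus a simulation-verified flag (x1 pinned at xi(u))."""
    x0 = np.asarray(x0, dtype=float)
    xi = camp_xi(instance, u)
    x0 = np.array([xi, x0[1], x0[2]])
    bound, p, cond14 = transient_bound(instance, u, x0[2])
    f = assemble_rhs(instance.model, instance, {"u": u})
    traj = simulate(f, x0, (0.0, 50.0), until_steady=True, max_time=2000.0)
    peak = float(np.max(traj.states[:, 2]))
    verified = bool(cond14 and peak <= bound * (1.0 + rtol_check) + 1e-9)
    return {"bound": bound, "p": p, "condition_holds": cond14,
            "peak": peak, "verified": verified}


# ---------------------------------------------------------------------------
# claims
# ---------------------------------------------------------------------------

def straddling_variant(instance, u: float, exists: bool, margin: float = 2.0):
    """Rescale both phosphodiesterase routes so the existence condition
    holds (ceiling = margin * worst-case production) or fails (ceiling =
    production / margin), keeping everything else fixed."""
    xi = camp_xi(instance, u)
    th2 = instance.fn("a23").scale
    lhs = float(instance.fn("d32")(th2) + instance.fn("a31")(th2) * xi)
    ceiling = _sup(instance.fn("b32")) * th2 + _sup(instance.fn("b33"))
    target = margin * lhs if exists else lhs / margin
    lam = target / ceiling
    out = instance.with_param(
        "b32", amplitude=lam * instance.param("b32", "amplitude"))
    out = out.with_param(
        "b33", amplitude=lam * instance.param("b33", "amplitude"))
    return out


def claim_existence_agreement(case, instance, seed) -> ClaimResult:
    """The closed existence condition agrees with multistart emptiness, on
    variants engineered to sit on both sides of the condition."""
    u = case.extras.get("u", DEFAULT_U)
    details = {}
    ok = True
    for exists in (True, False):
        var = straddling_variant(instance, u, exists)
        flag = camp_existence_check(var, u)
        f = assemble_rhs(var.model, var, {"u": u})
        eqs = find_equilibria(f, search_box(var, u), n_starts=80, seed=seed)
        agree = flag == (len(eqs) > 0) == exists
        ok &= agree
        details[f"exists={exists}"] = {"flag": bool(flag), "n_roots": len(eqs)}
    return ClaimResult("existence_agreement", ok, details)


def claim_monotone_in_u(case, instance, seed) -> ClaimResult:
    # enforce existence over the whole grid (the condition is monotone in
    # u, so enforcing it at the top of the grid is enough)
    instance = straddling_variant(instance, U_GRID[-1], exists=True)
    xs = []
    for u in U_GRID:
        eq = camp_equilibrium(instance, u)
        if eq is None:
            return ClaimResult("monotone_in_u", False, {"u_missing": u})
        xs.append(eq)
    xs = np.stack(xs)
    scale = np.maximum(np.max(np.abs(xs), axis=0), 1e-12)
    holds = bool(np.all(np.diff(xs, axis=0) >= -1e-9 * scale)
                 and np.all(xs[-1] > xs[0]))
    return ClaimResult("monotone_in_u", holds, {"equilibria": xs.tolist()})


def claim_transient_bound(case, instance, seed, n_x0: int = 5) -> ClaimResult:
    u = case.extras.get("u", DEFAULT_U)
    var = straddling_variant(instance, u, exists=True, margin=4.0)
    # enforce the dominance condition by lifting the saturating route alone
    bound, p, cond = transient_bound(var, u)
    if not cond:
        g_sup = _sup(var.fn("b33"))
        var = var.with_param(
            "b33", amplitude=2.0 * p * var.param("b33", "amplitude") / max(g_sup, 1e-300))
        bound, p, cond = transient_bound(var, u)
    th2 = var.fn("a23").scale
    rng = np.random.default_rng(seed)
    ok = cond
    peaks = []
    for _ in range(n_x0):
        x0 = np.array([0.0, rng.uniform(0, th2), rng.uniform(0, bound)])
        rep = camp_transient_bound(var, u, x0)
        peaks.append(rep["peak"])
        ok &= rep["verified"]
    return ClaimResult("transient_bound", bool(ok),
                       {"bound": bound, "peaks": peaks})


def claim_spike_exceeds_bound(case, instance, seed) -> ClaimResult:
    """The packaged dominance-violating instance produces a cAMP spike
    exceeding the bound that holds for the compliant default instance."""
    u = case.extras.get("u", DEFAULT_U)
    compliant_bound, _, cond_ok = transient_bound(case.default_instance, u)
    spike_inst = case.extras["spike_instance"]
    _, _, cond_spike = transient_bound(spike_inst, u)
    rep = camp_transient_bound(spike_inst, u, np.array([0.0, 0.0, 0.01]))
    holds = bool(cond_ok and not cond_spike
                 and rep["peak"] > compliant_bound)
    return ClaimResult("spike_exceeds_bound", holds,
                       {"compliant_bound": compliant_bound,
                        "spike_peak": rep["peak"]})


@register_case("camp")
def build() -> CaseStudy:
    model = load("camp")
    inst = sample_instance(model, frozen_config(DEFAULT_PARAMS), seed=0)
    spike = sample_instance(model, frozen_config(SPIKE_PARAMS), seed=0)
    cfg = SamplingConfig(
        term_params={
            "a1u": {"slope": (0.2, 5.0), "theta": (0.5, 5.0)},
            "b11": {"value": (0.2, 5.0)},
            "a23": {"slope": (0.2, 5.0), "theta": (0.5, 5.0)},
            "b22": {"value": (0.2, 5.0)},
            "d32": {"amplitude": (0.1, 10.0), "K": (0.2, 5.0)},
            "a31": {"amplitude": (0.1, 10.0), "K": (0.2, 5.0)},
            "b32": {"amplitude": (0.1, 10.0), "K": (0.2, 5.0)},
            "b33": {"amplitude": (0.1, 10.0), "K": (0.2, 5.0)},
        })
    claims = [
        Claim("existence_agreement", "existence condition == multistart "
              "non-emptiness on straddling variants", claim_existence_agreement),
        Claim("monotone_in_u", "equilibrium components increasing in u",
              claim_monotone_in_u),
        Claim("transient_bound", "cAMP spike bounded by the saturating-route "
              "level when the dominance condition holds", claim_transient_bound),
        Claim("spike_exceeds_bound", "violating the dominance condition "
              "breaks the spike bound", claim_spike_exceeds_bound,
              scope="default"),
    ]
    return CaseStudy(name="camp", model=model, default_instance=inst,
                     sampling_config=cfg, claims=claims,
                     default_inputs={"u": DEFAULT_U},
                     extras={"u": DEFAULT_U, "spike_instance": spike})
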