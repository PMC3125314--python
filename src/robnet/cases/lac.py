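"""Lac operon case study (reduced 3-state model).

Permease maturation chain x1 -> x2 imports inducer x3, which feeds back on
permease expression through the cooperative (basal-plus-Hill) rate f1.
Structurally the system is bounded, and the steady-state balance along the
x3-axis is one scalar equation, so equilibria come in odd runs: unique at
low and high external inducer u, three (stable / unstable / stable,
componentwise ordered) in an intermediate window for suitable kinetics.
Order cones around any equilibrium are invariant, so convergence from
below the low equilibrium has no overshoot.

The packaged default instance is a bistability witness located once by
seeded search over the sampling ranges and then frozen.
"""

from __future__ import annotations

import numpy as np

from ..certificates import crossing_count, sector_certificate
from ..dynamics import assemble_rhs, invariant_box, simulate
from ..ensemble import SamplingConfig, sample_instance
from ..equilibria import check_order, find_equilibria
from .base import CaseStudy, Claim, ClaimResult, frozen_config, load, register_case

# frozen bistability witness (delta_i = beta_1 = 1 time scale)
DEFAULT_PARAMS = {
    "c13": {"base": 0.05, "amplitude": 7.0, "K": 3.7, "H": 2.0},
    "b11": {"value": 1.0},
    "a21": {"value": 1.0},
    "b22": {"value": 1.0},
    "a32": {"amplitude": 3.5, "K": 1.0},
    "b32": {"amplitude": 2.0, "K": 4.0},
    "b33": {"value": 1.0},
}
#: readout coefficients for the slaved beta-galactosidase concentration
READOUT = {"gamma": 1.0, "delta4": 1.0}

U_GRID = tuple(np.geomspace(0.01, 100.0, 13))
U_BISTABLE = 4.0


def search_box(instance, u: float) -> np.ndarray:
    box = invariant_box(instance.model, instance, {"u": u}).finite(50.0)
    return 1.05 * box + 1e-6


def readout(instance, x3_star: float) -> float:
    """Slaved beta-galactosidase level gamma * f1(x3*) / delta4."""
    return READOUT["gamma"] * float(instance.fn("c13")(x3_star)) / READOUT["delta4"]


def lac_scan(instance, u_grid=U_GRID, n_starts: int = 150, seed: int = 0):
    """Per-u equilibrium count and stability pattern (multistart scan)."""
    out = []
    for k, u in enumerate(u_grid):
        f = assemble_rhs(instance.model, instance, {"u": u})
        eqs = find_equilibria(f, search_box(instance, u), n_starts=n_starts,
                              seed=seed + k)
        out.append({"u": float(u), "count": len(eqs),
                    "classes": [e.classification for e in eqs],
                    "equilibria": [e.state.tolist() for e in eqs]})
    return out


def claim_hysteresis_pattern(case, instance, seed) -> ClaimResult:
    scan = lac_scan(instance, seed=seed)
    counts = [s["count"] for s in scan]
    inside = counts[1:-1]
    three = [i for i, c in enumerate(inside) if c == 3]
    contiguous = bool(three) and three == list(range(three[0], three[-1] + 1))
    holds = (counts[0] == 1 and counts[-1] == 1 and contiguous
             and set(counts) <= {1, 3})
    return ClaimResult("hysteresis_pattern", holds, {"counts": counts})


def claim_sus_classification(case, instance, seed) -> ClaimResult:
    u = case.extras.get("u_bistable", U_BISTABLE)
    f = assemble_rhs(instance.model, instance, {"u": u})
    eqs = find_equilibria(f, search_box(instance, u), n_starts=200, seed=seed)
    classes = [e.classification for e in eqs]
    ordered, perm = check_order(eqs)
    holds = (len(eqs) == 3 and classes == ["stable", "unstable", "stable"]
             and ordered and perm == (0, 1, 2))
    return ClaimResult("sus_classification", holds,
                       {"classes": classes, "ordered": ordered,
                        "equilibria": [e.state.tolist() for e in eqs]})


def claim_no_overshoot_from_below(case, instance, seed) -> ClaimResult:
    """Trajectories started below the low stable equilibrium x^A converge
    to it without crossing any of its coordinates."""
    u = case.extras.get("u_bistable", U_BISTABLE)
    f = assemble_rhs(instance.model, instance, {"u": u})
    eqs = find_equilibria(f, search_box(instance, u), n_starts=200, seed=seed)
    if len(eqs) != 3:
        return ClaimResult("no_overshoot_from_below", False,
                           {"count": len(eqs)})
    xa = eqs[0].state
    rng = np.random.default_rng(seed)
    worst = 0
    final_ok = True
    for _ in range(3):
        x0 = rng.uniform(0.0, 1.0, size=3) * xa
        traj = simulate(f, x0, (0.0, 50.0), until_steady=True, max_time=4000.0)
        worst = max(worst, int(np.max(crossing_count(traj, xa))))
        final_ok &= bool(np.max(np.abs(traj.final - xa)) < 1e-5 * (1 + np.max(xa)))
    return ClaimResult("no_overshoot_from_below", worst == 0 and final_ok,
                       {"max_crossings": worst})


def claim_cone_invariance(case, instance, seed) -> ClaimResult:
    u = case.extras.get("u_bistable", U_BISTABLE)
    f = assemble_rhs(instance.model, instance, {"u": u})
    eqs = find_equilibria(f, search_box(instance, u), n_starts=200, seed=seed)
    if not eqs:
        return ClaimResult("cone_invariance", False, {})
    ok = True
    worst = -np.inf
    for eq in (eqs[0], eqs[-1]):
        rep = sector_certificate(f, eq.state, ("<=",) * 3,
                                 search_box(instance, u),
                                 n_boundary=1500, seed=seed)
        rep2 = sector_certificate(f, eq.state, (">=",) * 3,
                                  search_box(instance, u),
                                  n_boundary=1500, seed=seed + 1)
        ok &= rep.holds and rep2.holds
        worst = max(worst, rep.worst_margin, rep2.worst_margin)
    return ClaimResult("cone_invariance", bool(ok), {"worst_margin": worst})


@register_case("lac")
def build() -> CaseStudy:
    model = load("lac")
    inst = sample_instance(model, frozen_config(DEFAULT_PARAMS), seed=0)
    cfg = SamplingConfig(
        term_params={
            "c13": {"base": (0.02, 0.2), "amplitude": (1.0, 8.0),
                    "K": (0.5, 4.0)},
            "b11": {"value": (0.5, 2.0)},
            "a21": {"value": (0.5, 2.0)},
            "b22": {"value": (0.5, 2.0)},
            "a32": {"amplitude": (1.0, 10.0), "K": (0.5, 2.0)},
            "b32": {"amplitude": (0.2, 4.0), "K": (0.2, 4.0)},
            "b33": {"value": (0.5, 2.0)},
        })
    claims = [
        Claim("hysteresis_pattern", "equilibrium counts 1 -> 3 -> 1 along "
              "the u grid", claim_hysteresis_pattern, scope="default"),
        Claim("sus_classification", "three equilibria: stable/unstable/"
              "stable, componentwise ordered", claim_sus_classification,
              scope="default"),
        Claim("no_overshoot_from_below", "convergence to the low stable "
              "equilibrium from below has no overshoot",
              claim_no_overshoot_from_below, scope="default"),
        Claim("cone_invariance", "order cones at the outer stable "
              "equilibria are invariant", claim_cone_invariance,
              scope="default"),
    ]
    return CaseStudy(name="lac", model=model, default_instance=inst,
                     sampling_config=cfg, claims=claims,
                     default_inputs={"u": U_BISTABLE},
                     extras={"u_bistable": U_BISTABLE})
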