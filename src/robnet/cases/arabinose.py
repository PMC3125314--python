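"""L-arabinose feedforward case study.

Hierarchical two-gene cascade: AraC (x1) has basal plus CRP-activated
production, araBAD (x2) is activated by CRP (input u) and by AraC.  The
structural claims: a single stable equilibrium for every parameterization,
found iteratively along the hierarchy, and steady states monotonically
increasing in the CRP input.
"""

from __future__ import annotations

import numpy as np

from ..dynamics import assemble_rhs, invariant_box
from ..ensemble import SamplingConfig, sample_instance
from ..equilibria import find_equilibria, response_curve
from .base import CaseStudy, Claim, ClaimResult, frozen_config, load, register_case

DEFAULT_PARAMS = {
    "c1": {"value": 0.2},
    "c1u": {"amplitude": 1.0, "K": 1.0, "H": 2.0},
    "b11": {"value": 1.0},
    "c2u1": {"amplitude": 1.0, "K": 1.0, "H": 2.0},
    "b22": {"value": 1.0},
}
DEFAULT_MODS = {"c2u1": {"amplitude": 1.0, "K": 0.5}}
DEFAULT_U = 1.0
U_GRID = tuple(np.geomspace(0.01, 100.0, 7))


def cascade_equilibrium(instance, u: float) -> np.ndarray:
    """Closed-form sequential solution of the hierarchy."""
    c1 = instance.param("c1", "value")
    b11 = instance.param("b11", "value")
    b22 = instance.param("b22", "value")
    x1 = (c1 + float(instance.fn("c1u")(u))) / b11
    mod = instance.modulator_assignments["c2u1"][0]
    x2 = float(instance.fn("c2u1")(u)) * float(mod(x1)) / b22
    return np.array([x1, x2])


def claim_unique_stable(case, instance, seed) -> ClaimResult:
    u = case.extras.get("u", DEFAULT_U)
    f = assemble_rhs(instance.model, instance, {"u": u})
    box = invariant_box(instance.model, instance, {"u": u}).finite(10.0)
    eqs = find_equilibria(f, 1.05 * box + 1e-6, n_starts=100, seed=seed)
    ref = cascade_equilibrium(instance, u)
    holds = (len(eqs) == 1 and eqs[0].stable
             and np.allclose(eqs[0].state, ref, rtol=1e-6, atol=1e-9))
    return ClaimResult("unique_stable_equilibrium", holds,
                       {"n_equilibria": len(eqs), "reference": ref.tolist()})


def claim_monotone_in_u(case, instance, seed) -> ClaimResult:
    xs = np.stack([cascade_equilibrium(instance, u) for u in U_GRID])
    d = np.diff(xs, axis=0)
    # strict growth overall; consecutive steps may hit float resolution at
    # deep saturation, so only nondecrease is required pointwise
    scale = np.max(np.abs(xs), axis=0)
    holds = bool(np.all(d >= -1e-12 * scale) and np.all(xs[-1] > xs[0]))
    return ClaimResult("monotone_in_u", holds, {"equilibria": xs.tolist()})


def claim_monotone_in_u_multistart(case, instance, seed) -> ClaimResult:
    """Same monotonicity read off a multistart response curve (the slower,
    assumption-free route)."""
    rc = response_curve(instance.model, instance, "u", U_GRID,
                        n_starts=40, seed=seed, box_cap=50.0)
    if not np.all(rc.counts() == 1):
        return ClaimResult("monotone_in_u_multistart", False,
                           {"counts": rc.counts().tolist()})
    flags = rc.monotonicity(0)
    return ClaimResult("monotone_in_u_multistart", bool(np.all(flags == 1)),
                       {"flags": flags.tolist()})


@register_case("arabinose")
def build() -> CaseStudy:
    model = load("arabinose")
    inst = sample_instance(
        model, frozen_config(DEFAULT_PARAMS, modulator_params=DEFAULT_MODS),
        seed=0)
    claims = [
        Claim("unique_stable_equilibrium", "one stable equilibrium matching "
              "the sequential cascade solution", claim_unique_stable),
        Claim("monotone_in_u", "steady states strictly increasing in u",
              claim_monotone_in_u),
        Claim("monotone_in_u_multistart", "multistart response curve is a "
              "single increasing branch", claim_monotone_in_u_multistart,
              scope="default"),
    ]
    return CaseStudy(name="arabinose", model=model, default_instance=inst,
                     sampling_config=SamplingConfig(), claims=claims,
                     default_inputs={"u": DEFAULT_U}, extras={"u": DEFAULT_U})
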