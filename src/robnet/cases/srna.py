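"""sRNA silencing case study.

Two species annihilate through stoichiometric complex formation; the
structural claims are: a unique, exponentially stable equilibrium with
1-norm Lyapunov decrease at rate at least min(b11, b22), total
concentration trapped under kappa = (c1+c2)/min(b11, b22), monotone
no-oscillation convergence (each coordinate crosses its equilibrium value
at most once), invariant order sectors, and monotone steady-state response
to a step in either transcription rate (no under/overshoot).
"""

from __future__ import annotations

import numpy as np

from ..certificates import (
    PiecewiseLinearFunction,
    crossing_count,
    decay_rate,
    decrease_certificate,
    sector_certificate,
)
from ..dynamics import assemble_rhs, invariant_box, simulate
from ..ensemble import SamplingConfig
from ..equilibria import find_equilibria
from .base import CaseStudy, Claim, ClaimResult, frozen_config, load, register_case

UNIT_PARAMS = {
    "c1": {"value": 1.0}, "c2": {"value": 1.0},
    "b11": {"value": 1.0}, "b22": {"value": 1.0},
    "b12": {"slope": 1.0},
}


def kappa(instance) -> float:
    """Total-concentration trap (c1+c2)/min(b11,b22)."""
    return float(invariant_box(instance.model, instance).sum_bound)


def min_turnover(instance) -> float:
    return min(instance.param("b11", "value"), instance.param("b22", "value"))


def _horizon(instance) -> float:
    return 10.0 / min_turnover(instance)


def _find(instance, n_starts=200, seed=0):
    f = assemble_rhs(instance.model, instance)
    k = kappa(instance)
    eqs = find_equilibria(f, [k, k], n_starts=n_starts, seed=seed)
    return f, k, eqs


def claim_unique_equilibrium(case, instance, seed) -> ClaimResult:
    f, k, eqs = _find(instance, seed=seed)
    holds = len(eqs) == 1 and eqs[0].stable
    return ClaimResult("unique_equilibrium", holds,
                       {"n_equilibria": len(eqs),
                        "classes": [e.classification for e in eqs]})


def claim_lyapunov_decrease(case, instance, seed, n_samples=20000) -> ClaimResult:
    f, k, eqs = _find(instance, seed=seed)
    if len(eqs) != 1:
        return ClaimResult("lyapunov_decrease", False, {"n_equilibria": len(eqs)})
    V = PiecewiseLinearFunction.weighted_one_norm(eqs[0].state)
    rep = decrease_certificate(f, V, np.array([k, k]), n_samples=n_samples,
                               seed=seed)
    beta = min_turnover(instance)
    return ClaimResult("lyapunov_decrease",
                       rep.holds and rep.estimated_rate >= 0.999 * beta,
                       {"worst_margin": rep.worst_margin,
                        "estimated_rate": rep.estimated_rate, "beta": beta})


def claim_exponential_decay(case, instance, seed) -> ClaimResult:
    f, k, eqs = _find(instance, seed=seed)
    if len(eqs) != 1:
        return ClaimResult("exponential_decay", False, {})
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, 2.0 * k, size=2)
    traj = simulate(f, x0, (0.0, _horizon(instance)), until_steady=True,
                    max_time=4000.0 * _horizon(instance))
    V = PiecewiseLinearFunction.weighted_one_norm(eqs[0].state)
    rate, warn = decay_rate(traj.times, V.value(traj.states))
    beta = min_turnover(instance)
    return ClaimResult("exponential_decay", rate >= 0.9 * beta,
                       {"rate": rate, "beta": beta, "warning": warn})


def claim_no_oscillation(case, instance, seed) -> ClaimResult:
    f, k, eqs = _find(instance, seed=seed)
    if len(eqs) != 1:
        return ClaimResult("no_oscillation", False, {})
    rng = np.random.default_rng(seed)
    worst = 0
    for _ in range(3):
        x0 = rng.uniform(0.0, 2.0 * k, size=2)
        traj = simulate(f, x0, (0.0, _horizon(instance)), until_steady=True,
                        max_time=4000.0 * _horizon(instance))
        worst = max(worst, int(np.max(crossing_count(traj, eqs[0].state))))
    return ClaimResult("no_oscillation", worst <= 1, {"max_crossings": worst})


def claim_sector_invariance(case, instance, seed) -> ClaimResult:
    f, k, eqs = _find(instance, seed=seed)
    if len(eqs) != 1:
        return ClaimResult("sector_invariance", False, {})
    rep = sector_certificate(f, eqs[0].state, (">=", "<="),
                             np.array([k, k]), n_boundary=2000, seed=seed)
    rep2 = sector_certificate(f, eqs[0].state, ("<=", ">="),
                              np.array([k, k]), n_boundary=2000, seed=seed)
    return ClaimResult("sector_invariance", rep.holds and rep2.holds,
                       {"worst_margin": max(rep.worst_margin, rep2.worst_margin)})


def claim_step_response(case, instance, seed, factor: float = 2.0) -> ClaimResult:
    """Step c2 -> factor*c2 from steady state: x1* strictly down, x2*
    strictly up, and neither coordinate crosses its new equilibrium value
    before settling (no undershoot/overshoot)."""
    f, k, eqs = _find(instance, seed=seed)
    if len(eqs) != 1:
        return ClaimResult("step_response", False, {})
    old = eqs[0].state
    stepped = instance.with_param("c2", value=factor * instance.param("c2", "value"))
    f2 = assemble_rhs(stepped.model, stepped)
    k2 = kappa(stepped)
    eqs2 = find_equilibria(f2, [k2, k2], n_starts=120, seed=seed + 1)
    if len(eqs2) != 1:
        return ClaimResult("step_response", False, {"n_new": len(eqs2)})
    new = eqs2[0].state
    # strictness margins scale per coordinate: steady states of the two
    # species can differ by many orders of magnitude
    s0 = 1e-9 * (1.0 + abs(new[0]))
    s1 = 1e-9 * (1.0 + abs(new[1])) * 1e-3
    monotone = new[0] < old[0] - s0 * 1e-3 and new[1] > old[1] + s1
    traj = simulate(f2, old, (0.0, _horizon(stepped)), until_steady=True,
                    max_time=4000.0 * _horizon(stepped))
    crossings = crossing_count(traj, new)
    return ClaimResult("step_response", monotone and int(np.max(crossings)) == 0,
                       {"old": old.tolist(), "new": new.tolist(),
                        "crossings": crossings.tolist()})


def proposition_report(instance, seed: int = 0, n_cert_samples: int = 20000,
                       step_factor: float = 2.0) -> dict:
    """All structural-stability checks for one instance, sharing a single
    multistart root find: equilibrium uniqueness, 1-norm decrease on
    [0, kappa]^2, fitted decay rate vs min(b11, b22), per-coordinate
    crossing counts, sector invariance, and the step-response monotonicity
    with zero under/overshoot."""
    f, k, eqs = _find(instance, seed=seed)
    out = {"kappa": k, "n_equilibria": len(eqs)}
    if len(eqs) != 1:
        out["holds"] = False
        return out
    xs = eqs[0].state
    beta = min_turnover(instance)
    V = PiecewiseLinearFunction.weighted_one_norm(xs)
    cert = decrease_certificate(f, V, np.array([k, k]),
                                n_samples=n_cert_samples, seed=seed)
    out["decrease_holds"] = bool(cert.holds)
    out["estimated_rate"] = cert.estimated_rate

    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, 2.0 * k, size=2)
    traj = simulate(f, x0, (0.0, _horizon(instance)), until_steady=True,
                    max_time=4000.0 * _horizon(instance))
    rate, warn = decay_rate(traj.times, V.value(traj.states))
    out["decay_rate"] = rate
    out["decay_ok"] = rate >= 0.9 * beta
    out["max_crossings"] = int(np.max(crossing_count(traj, xs)))

    sect = sector_certificate(f, xs, (">=", "<="), np.array([k, k]),
                              n_boundary=2000, seed=seed)
    out["sector_holds"] = bool(sect.holds)

    step = claim_step_response(None, instance, seed, factor=step_factor)
    out["step_ok"] = bool(step)
    out["holds"] = bool(
        cert.holds and cert.estimated_rate >= 0.999 * beta and out["decay_ok"]
        and out["max_crossings"] <= 1 and sect.holds and step)
    out["beta"] = beta
    return out


@register_case("srna")
def build() -> CaseStudy:
    model = load("srna")
    default = frozen_config(UNIT_PARAMS)
    from ..ensemble import sample_instance
    inst = sample_instance(model, default, seed=0)
    claims = [
        Claim("unique_equilibrium", "multistart root finding returns exactly "
              "one equilibrium, stable", claim_unique_equilibrium),
        Claim("lyapunov_decrease", "1-norm generalized derivative negative on "
              "[0,kappa]^2 with rate >= min(b11,b22)", claim_lyapunov_decrease),
        Claim("exponential_decay", "fitted decay rate of V >= 0.9*min(b11,b22)",
              claim_exponential_decay),
        Claim("no_oscillation", "each coordinate crosses its equilibrium at "
              "most once", claim_no_oscillation),
        Claim("sector_invariance", "order sectors through the equilibrium are "
              "invariant", claim_sector_invariance),
        Claim("step_response", "step in c2: x1* down, x2* up, no under/"
              "overshoot", claim_step_response),
    ]
    return CaseStudy(name="srna", model=model, default_instance=inst,
                     sampling_config=SamplingConfig(), claims=claims)
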