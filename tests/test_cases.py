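"""Case-study structure and the semi-analytic helpers."""

import numpy as np
import pytest

import robnet as rn
from robnet.cases import (
    build_case,
    camp_equilibrium,
    camp_existence_check,
    camp_xi,
    case_names,
    lac_scan,
    with_feedback,
)
from robnet.cases.arabinose import cascade_equilibrium
from robnet.cases.camp import straddling_variant, transient_bound
from robnet.cases.mapk import cascade_state, equilibria_for, scalar_equilibria
from robnet.cases.srna import kappa


def test_five_cases_registered():
    assert case_names() == ["arabinose", "camp", "lac", "mapk", "srna"]


def test_unknown_case_raises():
    with pytest.raises(KeyError):
        build_case("chemotaxis")


@pytest.mark.parametrize("name", case_names())
def test_case_models_validate_and_instances_verify(cases, name):
    case = cases(name)
    assert rn.validate_model(case.model).passed
    for term in case.model.terms:
        f = case.default_instance.assignments[term.name]
        assert rn.verify_property(f, term.tag).passed, term.name


def test_srna_case_shape(cases):
    case = cases("srna")
    assert case.model.n_states == 2 and len(case.model.terms) == 6
    b12 = next(t for t in case.model.terms if t.name == "b12")
    b21 = next(t for t in case.model.terms if t.name == "b21")
    assert b12.coupling_id == b21.coupling_id == "k"
    assert kappa(case.default_instance) == pytest.approx(2.0)


def test_mapk_case_is_reduced_to_five_states(cases):
    case = cases("mapk")
    assert case.model.n_states == 5
    assert case.extras["full_model"].n_states == 7
    assert "c10" in case.extras["existence_condition"]


def test_lac_case_reports_readout_not_state(cases):
    case = cases("lac")
    assert case.model.n_states == 3
    from robnet.cases.lac import readout
    assert readout(case.default_instance, 1.0) > 0


def test_arabinose_cascade_formula_matches_root_finding(cases):
    case = cases("arabinose")
    inst = case.default_instance
    ref = cascade_equilibrium(inst, 1.0)
    f = rn.assemble_rhs(case.model, inst, {"u": 1.0})
    assert np.max(np.abs(f(0.0, ref))) < 1e-12


# --- cAMP helpers -----------------------------------------------------------

def test_camp_xi_zero_at_zero_input(cases):
    assert camp_xi(cases("camp").default_instance, 0.0) == 0.0


def test_camp_xi_increasing_and_saturating(cases):
    inst = cases("camp").default_instance
    grid = np.geomspace(0.01, 1e6, 12)
    vals = [camp_xi(inst, u) for u in grid]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    theta = inst.fn("a1u").scale
    assert vals[-1] <= theta
    # saturation: pushing u a decade further moves xi by < 1e-3 relative
    assert camp_xi(inst, 1e7) - vals[-1] < 1e-3 * theta


def test_camp_equilibrium_matches_field_root(cases):
    inst = cases("camp").default_instance
    eq = camp_equilibrium(inst, 2.0)
    f = rn.assemble_rhs(inst.model, inst, {"u": 2.0})
    assert np.max(np.abs(f(0.0, eq))) < 1e-10


def test_camp_existence_flag_monotone_in_u(cases):
    """Once production outgrows the degradation ceiling the flag must stay
    false for all larger u."""
    inst = cases("camp").default_instance
    var = straddling_variant(inst, 1.0, exists=False)
    flags = [camp_existence_check(var, u) for u in np.geomspace(0.01, 100, 9)]
    dropped = False
    for fl in flags:
        if not fl:
            dropped = True
        assert not (dropped and fl)


def test_camp_spike_instance_violates_dominance(cases):
    case = cases("camp")
    _, _, ok_default = transient_bound(case.default_instance, 2.0)
    _, _, ok_spike = transient_bound(case.extras["spike_instance"], 2.0)
    assert ok_default and not ok_spike


# --- lac helpers ------------------------------------------------------------

def test_lac_scan_reports_counts(cases):
    inst = cases("lac").default_instance
    scan = lac_scan(inst, u_grid=[0.05, 4.0, 80.0], n_starts=120, seed=0)
    assert [s["count"] for s in scan] == [1, 3, 1]


# --- MAPK helpers -----------------------------------------------------------

def test_cascade_state_is_a_field_root_at_scalar_equilibrium(cases):
    inst = cases("mapk").default_instance
    var = with_feedback(inst, "constant", 0.0)
    roots = scalar_equilibria(var)
    assert roots.size == 1
    x = cascade_state(var, float(roots[0]))
    f = rn.assemble_rhs(var.model, var)
    assert np.max(np.abs(f(0.0, x))) < 1e-8


def test_mapk_multistart_agrees_with_scalar_oracle_counts(cases):
    inst = cases("mapk").default_instance
    for family, mu in [("constant", 0.3), ("constant", 0.02),
                       ("unbounded_increasing", 1.0)]:
        var = with_feedback(inst, family, mu)
        nsc = scalar_equilibria(var).size
        eqs = equilibria_for(var, n_starts=80, seed=3)
        assert len(eqs) == nsc, (family, mu)


def test_with_feedback_swaps_tag_and_family(cases):
    inst = cases("mapk").default_instance
    var = with_feedback(inst, "unbounded_increasing", 2.0)
    a17 = next(t for t in var.model.terms if t.name == "a17")
    assert a17.tag == rn.PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED
    assert var.assignments["a17"].parameters["slope"] == 2.0
    assert rn.validate_model(var.model).passed


def test_mapk_partial_order_of_bistable_equilibria(cases):
    """Phosphorylated tiers rise along the branch order while the
    unphosphorylated pools fall."""
    inst = cases("mapk").default_instance
    var = with_feedback(inst, "constant", 0.3)
    eqs = equilibria_for(var, n_starts=120, seed=1)
    assert len(eqs) == 3
    from robnet.equilibria import check_order
    fwd, _ = check_order(eqs, subset=[0, 2, 4])
    rev, _ = check_order(eqs, subset=[0, 1, 3], directions={1: -1, 3: -1})
    assert fwd and rev
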