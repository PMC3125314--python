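"""Function library: shape verification, derivatives, parameter checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robnet.functions import (
    FAMILY_DEFAULTS,
    FAMILY_TAGS,
    ParameterError,
    make_function,
    verify_property,
)
from robnet.tags import PropertyTag as P


@pytest.mark.parametrize("family", sorted(FAMILY_DEFAULTS))
def test_default_parameterization_satisfies_documented_tag(family):
    rep = verify_property(make_function(family), FAMILY_TAGS[family])
    assert rep.passed, rep.violated


# (family, params, claimed tag, predicate expected to fail)
MISPAIRS = [
    ("hill_sigmoid", {"H": 1.0}, P.SIGMOIDAL, "f'(0) = 0"),
    ("constant", {}, P.SIGMOIDAL, "f(0) = 0"),
    ("mm_saturating", {}, P.SIGMOIDAL, "f'(0) = 0"),
    ("comp_hill", {"H": 1.0}, P.COMPLEMENTARY_SIGMOIDAL, "f'(0) = 0"),
    ("decreasing_null", {}, P.DECREASING_EXACTLY_NULL,
     "f = 0 above threshold"),
    ("linear_unbounded", {}, P.INCREASING_ASYMPTOTICALLY_CONSTANT,
     "f(inf) finite"),
    ("threshold_decreasing", {}, P.COMPLEMENTARY_SIGMOIDAL, "f'(0) = 0"),
    ("hill_sigmoid", {"H": 2.0}, P.INCREASING_ASYMPTOTICALLY_CONSTANT,
     "f' decreasing"),
    ("mm_saturating", {}, P.INCREASING_ASYMPTOTICALLY_UNBOUNDED,
     "f(inf) = +inf"),
]


@pytest.mark.parametrize("family,params,tag,predicate", MISPAIRS)
def test_documented_mispairs_fail_with_named_predicate(family, params, tag,
                                                       predicate):
    rep = verify_property(make_function(family, params), tag)
    assert not rep.passed
    assert predicate in rep.violated


def test_michaelis_menten_form_is_the_hill_exponent_one_case():
    # the same function rejected as a sigmoid is accepted as
    # increasing-asymptotically-constant
    f = make_function("hill_sigmoid", {"H": 1.0})
    assert not verify_property(f, P.SIGMOIDAL).passed
    assert verify_property(f, P.INCREASING_ASYMPTOTICALLY_CONSTANT).passed


def test_hill_point_values():
    f = make_function("hill_sigmoid", {"K": 1.0, "H": 2.0})
    assert float(f(1.0)) == pytest.approx(0.5)
    assert float(f(0.0)) == 0.0
    g = make_function("comp_hill", {"K": 1.0, "H": 2.0})
    assert float(g(0.0)) == pytest.approx(1.0)


@pytest.mark.parametrize("family", sorted(FAMILY_DEFAULTS))
def test_finite_difference_derivative_matches_analytic(family):
    f = make_function(family)
    x = np.geomspace(1e-2, 1e2, 50)
    fd = f.derivative(x)
    an = f.analytic_derivative(x)
    scale = np.max(np.abs(an)) + 1e-12
    assert np.max(np.abs(fd - an)) / scale < 1e-5


@pytest.mark.parametrize("family", sorted(FAMILY_DEFAULTS))
def test_scalar_fast_path_matches_vectorized(family):
    f = make_function(family)
    s = f.as_scalar()
    xs = np.geomspace(1e-3, 1e3, 23)
    vec = np.asarray(f(xs))
    for x, v in zip(xs, vec):
        assert s(float(x)) == pytest.approx(v, rel=1e-12, abs=1e-300)


@pytest.mark.parametrize("family,bad", [
    ("hill_sigmoid", {"K": -1.0}),
    ("hill_sigmoid", {"H": 0.5}),
    ("mm_saturating", {"amplitude": -2.0}),
    ("threshold_decreasing", {"theta": 0.0}),
    ("linear_unbounded", {"slope": -1.0}),
    ("constant", {"value": -0.1}),
])
def test_invalid_parameters_raise(family, bad):
    with pytest.raises(ParameterError):
        make_function(family, bad)


def test_unknown_family_raises():
    with pytest.raises(ParameterError, match="unknown family"):
        make_function("not_a_family", {})


def test_verify_property_is_deterministic():
    f = make_function("hill_sigmoid")
    r1 = verify_property(f, P.SIGMOIDAL, grid_max=500.0)
    r2 = verify_property(f, P.SIGMOIDAL, grid_max=500.0)
    assert r1.passed == r2.passed and r1.violated == r2.violated


@settings(deadline=None, max_examples=25, derandomize=True)
@given(K=st.floats(0.05, 50.0), H=st.integers(2, 4),
       A=st.floats(0.1, 10.0))
def test_hill_sigmoid_passes_sigmoidal_across_parameters(K, H, A):
    f = make_function("hill_sigmoid", {"K": K, "H": float(H), "amplitude": A})
    assert verify_property(f, P.SIGMOIDAL).passed


@settings(deadline=None, max_examples=25, derandomize=True)
@given(theta=st.floats(0.1, 20.0), slope=st.floats(0.1, 10.0))
def test_smoothed_hinge_is_exactly_null_and_c1(theta, slope):
    f = make_function("threshold_decreasing",
                      {"theta": theta, "slope": slope})
    assert verify_property(f, P.DECREASING_EXACTLY_NULL).passed
    assert float(f(theta)) == 0.0
    assert float(f(2.0 * theta)) == 0.0
    # C1 continuity at the blend edges
    eps = theta / 20.0
    for edge in (theta - eps, theta):
        d_lo = f.analytic_derivative(edge - 1e-9 * theta)
        d_hi = f.analytic_derivative(edge + 1e-9 * theta)
        assert float(d_lo) == pytest.approx(float(d_hi), abs=1e-6 * slope)
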