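"""Parametric scalar-function families and numerical shape verification.

A :class:`ParametricFunction` is one concrete realization of a property tag:
a Hill sigmoid, a Michaelis-Menten saturation, a smoothed threshold hinge,
and so on.  ``verify_property`` checks, on a geometric grid, whether a given
function actually satisfies the predicate list of a claimed tag (sign,
monotonicity, value and slope at the origin, limit behaviour, unimodality of
the derivative).  Qualitative models only promise tags; this module is what
makes those promises falsifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .tags import PropertyTag

__all__ = [
    "ParametricFunction",
    "make_function",
    "verify_property",
    "PropertyReport",
    "FAMILY_DEFAULTS",
    "FAMILY_TAGS",
    "TAG_DEFAULT_FAMILY",
]

_EPS = np.finfo(float).eps


class ParameterError(ValueError):
    """Raised when family parameters violate their positivity constraints."""


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def _req(params: dict, name: str, default=None):
    if name in params:
        return float(params[name])
    if default is not None:
        return float(default)
    raise ParameterError(f"missing parameter {name!r}")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _hinge_smooth(x, slope, theta):
    """C1 hinge: slope*(theta-x) below theta, exactly 0 above, cubic blend
    on [theta-eps, theta] with eps = theta/20 so smoothness (A1) holds."""
    x = np.asarray(x, dtype=float)
    eps = theta / 20.0
    t = np.clip((theta - x) / eps, 0.0, None)
    blend = slope * eps * (2.0 * t**2 - t**3)
    linear = slope * (theta - x)
    out = np.where(x >= theta, 0.0, np.where(x <= theta - eps, linear, blend))
    return out


def _hinge_smooth_d(x, slope, theta):
    x = np.asarray(x, dtype=float)
    eps = theta / 20.0
    t = np.clip((theta - x) / eps, 0.0, None)
    blend = -slope * (4.0 * t - 3.0 * t**2)
    out = np.where(x >= theta, 0.0, np.where(x <= theta - eps, -slope, blend))
    return out


# family_id -> (validate(params) -> canonical params, f(x, p), f'(x, p))
_FAMILIES: dict[str, tuple[Callable, Callable, Callable]] = {}


def _family(name):
    def deco(builder):
        _FAMILIES[name] = builder()
        return builder
    return deco


@_family("constant")
def _constant():
    def val(p):
        v = _req(p, "value")
        _check(v >= 0, "constant value must be >= 0")
        return {"value": v}
    return (val, lambda x, p: np.full_like(np.asarray(x, float), p["value"]),
            lambda x, p: np.zeros_like(np.asarray(x, float)))


def _hill(x, A, K, H):
    x = np.asarray(x, dtype=float)
    xh = np.power(np.clip(x, 0.0, None), H)
    return A * xh / (K**H + xh)


def _hill_d(x, A, K, H):
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, _EPS, None)
    xh = np.power(xc, H)
    return A * H * K**H * np.power(xc, H - 1.0) / (K**H + xh) ** 2


def _hill_params(p):
    A = _req(p, "amplitude", 1.0)
    K = _req(p, "K")
    H = _req(p, "H", 2.0)
    _check(K > 0, "K must be > 0")
    _check(H >= 1, "Hill exponent H must be >= 1")
    _check(A >= 0, "amplitude must be >= 0")
    return {"amplitude": A, "K": K, "H": H}


@_family("hill_sigmoid")
def _hill_sigmoid():
    return (_hill_params,
            lambda x, p: _hill(x, p["amplitude"], p["K"], p["H"]),
            lambda x, p: _hill_d(x, p["amplitude"], p["K"], p["H"]))


def _comp_hill_val(x, A, K, H):
    x = np.asarray(x, dtype=float)
    xh = np.power(np.clip(x, 0.0, None), H)
    return A * K**H / (K**H + xh)


@_family("comp_hill")
def _comp_hill():
    return (_hill_params,
            lambda x, p: _comp_hill_val(x, p["amplitude"], p["K"], p["H"]),
            lambda x, p: -_hill_d(x, p["amplitude"], p["K"], p["H"]))


def _const_plus(base):
    fval, ffun, fder = _FAMILIES[base]

    def val(p):
        out = fval(p)
        c0 = _req(p, "base", 0.1)
        _check(c0 > 0, "base constant must be > 0")
        out["base"] = c0
        return out

    return (val, lambda x, p: p["base"] + ffun(x, p), fder)


@_family("constant_plus_hill")
def _constant_plus_hill():
    return _const_plus("hill_sigmoid")


@_family("constant_plus_comp_hill")
def _constant_plus_comp_hill():
    return _const_plus("comp_hill")


@_family("mm_saturating")
def _mm_saturating():
    def val(p):
        A = _req(p, "amplitude", 1.0)
        K = _req(p, "K")
        _check(K > 0, "K must be > 0")
        _check(A > 0, "amplitude must be > 0")
        return {"amplitude": A, "K": K}
    return (val,
            lambda x, p: p["amplitude"] * np.asarray(x, float) / (p["K"] + np.asarray(x, float)),
            lambda x, p: p["amplitude"] * p["K"] / (p["K"] + np.asarray(x, float)) ** 2)


@_family("decreasing_null")
def _decreasing_null():
    def val(p):
        A = _req(p, "amplitude", 1.0)
        K = _req(p, "K")
        _check(K > 0, "K must be > 0")
        _check(A > 0, "amplitude must be > 0")
        return {"amplitude": A, "K": K}
    return (val,
            lambda x, p: p["amplitude"] * p["K"] / (p["K"] + np.asarray(x, float)),
            lambda x, p: -p["amplitude"] * p["K"] / (p["K"] + np.asarray(x, float)) ** 2)


@_family("threshold_decreasing")
def _threshold_decreasing():
    def val(p):
        s = _req(p, "slope")
        th = _req(p, "theta")
        _check(s > 0, "slope must be > 0")
        _check(th > 0, "theta must be > 0")
        return {"slope": s, "theta": th}
    return (val,
            lambda x, p: _hinge_smooth(x, p["slope"], p["theta"]),
            lambda x, p: _hinge_smooth_d(x, p["slope"], p["theta"]))


@_family("linear_unbounded")
def _linear_unbounded():
    def val(p):
        s = _req(p, "slope")
        _check(s > 0, "slope must be > 0")
        return {"slope": s}
    return (val,
            lambda x, p: p["slope"] * np.asarray(x, dtype=float),
            lambda x, p: np.full_like(np.asarray(x, dtype=float), p["slope"]))


#: Default parameterization of every family (unit scales).
FAMILY_DEFAULTS: dict[str, dict] = {
    "constant": {"value": 1.0},
    "hill_sigmoid": {"amplitude": 1.0, "K": 1.0, "H": 2.0},
    "comp_hill": {"amplitude": 1.0, "K": 1.0, "H": 2.0},
    "constant_plus_hill": {"base": 0.1, "amplitude": 1.0, "K": 1.0, "H": 2.0},
    "constant_plus_comp_hill": {"base": 0.1, "amplitude": 1.0, "K": 1.0, "H": 2.0},
    "mm_saturating": {"amplitude": 1.0, "K": 1.0},
    "decreasing_null": {"amplitude": 1.0, "K": 1.0},
    "threshold_decreasing": {"slope": 1.0, "theta": 1.0},
    "linear_unbounded": {"slope": 1.0},
}

#: Documented tag of each family at its default parameters.
FAMILY_TAGS: dict[str, PropertyTag] = {
    "constant": PropertyTag.POSITIVE_CONSTANT,
    "hill_sigmoid": PropertyTag.SIGMOIDAL,
    "comp_hill": PropertyTag.COMPLEMENTARY_SIGMOIDAL,
    "constant_plus_hill": PropertyTag.CONSTANT_SIGMOIDAL,
    "constant_plus_comp_hill": PropertyTag.CONSTANT_COMPLEMENTARY_SIGMOIDAL,
    "mm_saturating": PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT,
    "decreasing_null": PropertyTag.DECREASING_ASYMPTOTICALLY_NULL,
    "threshold_decreasing": PropertyTag.DECREASING_EXACTLY_NULL,
    "linear_unbounded": PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED,
}

#: Family used by the ensemble sampler when a term only states a tag.
TAG_DEFAULT_FAMILY: dict[PropertyTag, str] = {
    PropertyTag.NONNEGATIVE_CONSTANT: "constant",
    PropertyTag.POSITIVE_CONSTANT: "constant",
    PropertyTag.SIGMOIDAL: "hill_sigmoid",
    PropertyTag.COMPLEMENTARY_SIGMOIDAL: "comp_hill",
    PropertyTag.CONSTANT_SIGMOIDAL: "constant_plus_hill",
    PropertyTag.CONSTANT_COMPLEMENTARY_SIGMOIDAL: "constant_plus_comp_hill",
    PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT: "mm_saturating",
    PropertyTag.DECREASING_ASYMPTOTICALLY_NULL: "decreasing_null",
    PropertyTag.DECREASING_EXACTLY_NULL: "threshold_decreasing",
    PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED: "linear_unbounded",
}


@dataclass(frozen=True)
class ParametricFunction:
    """A concrete scalar function realizing one property tag.

    Evaluation is vectorized over numpy arrays and restricted to x >= 0.
    ``derivative`` uses an adaptive central difference; the analytic
    derivative of each packaged family is available for cross-checks.
    """

    family_id: str
    parameters: dict = field(default_factory=dict)
    claimed_tag: PropertyTag | None = None

    def __call__(self, x):
        _, f, _ = _FAMILIES[self.family_id]
        return f(x, self.parameters)

    def derivative(self, x):
        """Central finite difference with step ~ eps^(1/3) * (1 + |x|)."""
        x = np.asarray(x, dtype=float)
        h = _EPS ** (1.0 / 3.0) * (1.0 + np.abs(x))
        lo = np.clip(x - h, 0.0, None)
        hi = x + h
        return (self(hi) - self(lo)) / (hi - lo)

    def analytic_derivative(self, x):
        _, _, d = _FAMILIES[self.family_id]
        return d(x, self.parameters)

    def as_scalar(self) -> Callable[[float], float]:
        """Fast float->float closure (used in ODE right-hand sides)."""
        p = self.parameters
        fam = self.family_id
        if fam == "constant":
            v = p["value"]
            return lambda x: v
        if fam in ("hill_sigmoid", "comp_hill", "constant_plus_hill",
                   "constant_plus_comp_hill"):
            A, K, H = p["amplitude"], p["K"], p["H"]
            KH = K ** H
            c0 = p.get("base", 0.0)
            comp = fam in ("comp_hill", "constant_plus_comp_hill")
            if comp:
                def fn(x, A=A, KH=KH, H=H, c0=c0):
                    xh = (x if x > 0.0 else 0.0) ** H
                    return c0 + A * KH / (KH + xh)
            else:
                def fn(x, A=A, KH=KH, H=H, c0=c0):
                    xh = (x if x > 0.0 else 0.0) ** H
                    return c0 + A * xh / (KH + xh)
            return fn
        if fam == "mm_saturating":
            A, K = p["amplitude"], p["K"]
            return lambda x, A=A, K=K: A * (x if x > 0.0 else 0.0) / (K + (x if x > 0.0 else 0.0))
        if fam == "decreasing_null":
            A, K = p["amplitude"], p["K"]
            return lambda x, A=A, K=K: A * K / (K + (x if x > 0.0 else 0.0))
        if fam == "threshold_decreasing":
            s, th = p["slope"], p["theta"]
            eps = th / 20.0

            def fn(x, s=s, th=th, eps=eps):
                if x >= th:
                    return 0.0
                if x <= th - eps:
                    return s * (th - x)
                t = (th - x) / eps
                return s * eps * (2.0 * t * t - t * t * t)
            return fn
        if fam == "linear_unbounded":
            s = p["slope"]
            return lambda x, s=s: s * (x if x > 0.0 else 0.0)
        return lambda x: float(self(x))  # pragma: no cover - fallback

    @property
    def scale(self) -> float:
        """Characteristic argument scale (half-saturation / threshold)."""
        p = self.parameters
        return float(p.get("K") or p.get("theta") or 1.0)

    def to_dict(self) -> dict:
        return {
            "family": self.family_id,
            "parameters": dict(self.parameters),
            "tag": self.claimed_tag.value if self.claimed_tag else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricFunction":
        tag = PropertyTag(d["tag"]) if d.get("tag") else None
        return make_function(d["family"], d.get("parameters", {}), tag)


def make_function(family_id: str, parameters: dict | None = None,
                  claimed_tag: PropertyTag | None = None) -> ParametricFunction:
    """Build a ParametricFunction, validating family-specific constraints."""
    if family_id not in _FAMILIES:
        raise ParameterError(f"unknown family {family_id!r}; "
                             f"known: {sorted(_FAMILIES)}")
    validate, _, _ = _FAMILIES[family_id]
    merged = dict(FAMILY_DEFAULTS.get(family_id, {}))
    merged.update(parameters or {})
    canon = validate(merged)
    if claimed_tag is None:
        claimed_tag = FAMILY_TAGS.get(family_id)
    return ParametricFunction(family_id, canon, claimed_tag)


# ---------------------------------------------------------------------------
# property verification
# ---------------------------------------------------------------------------

@dataclass
class PropertyReport:
    tag: PropertyTag
    passed: bool
    violated: list[str]
    grid_max: float

    def __bool__(self) -> bool:
        return self.passed


def _unimodal(values: np.ndarray, mode: str, dead_band: float) -> bool:
    """True if the sequence rises to a single max (mode='max') or falls to a
    single min (mode='min'), up to a dead band on second differences."""
    v = values if mode == "max" else -values
    d = np.diff(v)
    band = dead_band * max(np.max(np.abs(v)), 1e-300)
    signs = np.where(d > band, 1, np.where(d < -band, -1, 0))
    signs = signs[signs != 0]
    if signs.size == 0:
        return True
    flips = np.sum(np.diff(signs) != 0)
    # admissible patterns: all up, all down, up-then-down
    return flips <= 1 and not (signs[0] == -1 and signs[-1] == 1)


def verify_property(f: ParametricFunction | Callable, tag: PropertyTag,
                    grid_max: float | None = None,
                    n_grid: int = 400) -> PropertyReport:
    """Check the predicate list of ``tag`` for ``f`` on a geometric grid.

    Limits at infinity are probed by comparing ``f(grid_max)`` with
    ``f(10*grid_max)`` (relative tolerance 1e-3); unbounded growth (the
    increasing-asymptotically-unbounded class) by the same pair of probes.
    """
    tag = PropertyTag(tag)
    scale = f.scale if isinstance(f, ParametricFunction) else 1.0
    if grid_max is None:
        grid_max = 1e4 * scale
    grid = np.concatenate([
        [0.0],
        np.geomspace(1e-4 * scale, grid_max, n_grid),
    ])
    y = np.asarray(f(grid), dtype=float)
    y_far = float(np.asarray(f(np.asarray([10.0 * grid_max]))).ravel()[0])

    violated: list[str] = []
    if not np.all(np.isfinite(y)) or not np.isfinite(y_far):
        bad = grid[~np.isfinite(y)]
        raise FloatingPointError(
            f"non-finite evaluation at x={bad[:3]!r}")

    ymax = float(np.max(np.abs(y)))
    tol = 1e-9 * max(ymax, 1e-300)  # scales with the function, not with 1
    if np.any(y < -tol):
        violated.append("f >= 0")

    y0 = float(y[0])
    y_end = float(y[-1])
    diffs = np.diff(y)

    def nondecreasing():
        if np.any(diffs < -tol):
            violated.append("f non-decreasing")

    def nonincreasing():
        if np.any(diffs > tol):
            violated.append("f non-increasing")

    strict_tol = 1e-13 * max(ymax, 1e-300)

    def strictly_increasing():
        if np.any(diffs <= strict_tol):
            violated.append("f' > 0")

    def strictly_decreasing_to(limit_name):
        if np.any(diffs >= -strict_tol):
            violated.append("f' < 0")

    def zero_at_origin():
        if abs(y0) > tol:
            violated.append("f(0) = 0")

    def positive_at_origin():
        if y0 <= tol:
            violated.append("f(0) > 0")

    def zero_slope_at_origin():
        # compare the near-origin secant slope with the characteristic
        # slope f(grid_max)/scale; a true sigmoid (H >= 2) is quadratic
        # near 0 and passes, a Michaelis-Menten form does not
        x_small = 1e-4 * scale
        slope0 = abs(float(np.asarray(f(np.asarray([x_small]))).ravel()[0]) - y0) / x_small
        char = max(abs(y_end - y0), abs(y0), tol) / scale
        if slope0 > 1e-2 * char:
            violated.append("f'(0) = 0")

    def finite_positive_limit():
        if y_end <= tol:
            violated.append("f(inf) > 0")
        if abs(y_far - y_end) > 1e-3 * max(abs(y_end), tol):
            violated.append("f(inf) finite")

    def null_limit():
        if abs(y_end) > 1e-3 * max(abs(y0), tol) or abs(y_far) > abs(y_end) + tol:
            violated.append("f(inf) = 0")

    def exactly_null_tail():
        if abs(y_end) > 1e-9 * max(abs(y0), 1e-300) or abs(y_far) > 1e-9 * max(abs(y0), 1e-300):
            violated.append("f = 0 above threshold")

    def unbounded_growth():
        if not (y_far >= 1.5 * max(y_end, tol) and y_end > tol):
            violated.append("f(inf) = +inf")

    interior = grid[1:]
    if isinstance(f, ParametricFunction):
        deriv = np.asarray(f.derivative(interior), dtype=float)
    else:  # plain callable: central differences
        h = _EPS ** (1.0 / 3.0) * (1.0 + interior)
        deriv = (np.asarray(f(interior + h)) - np.asarray(f(np.clip(interior - h, 0, None)))) / (
            interior + h - np.clip(interior - h, 0, None))

    def derivative_unique_max():
        if not _unimodal(deriv, "max", 1e-8):
            violated.append("f' has a unique maximum")

    def derivative_unique_min():
        if not _unimodal(deriv, "min", 1e-8):
            violated.append("f' has a unique minimum")

    def derivative_decreasing():
        dband = 1e-8 * max(np.max(np.abs(deriv)), 1e-300)
        if np.any(np.diff(deriv) > dband):
            violated.append("f' decreasing")

    def derivative_increasing():
        dband = 1e-8 * max(np.max(np.abs(deriv)), 1e-300)
        if np.any(np.diff(deriv) < -dband):
            violated.append("f' increasing")

    def constant_value():
        if ymax > 0 and (np.max(y) - np.min(y)) > 1e-9 * (1.0 + ymax):
            violated.append("f constant")

    if tag is PropertyTag.NONNEGATIVE_CONSTANT:
        constant_value()
    elif tag is PropertyTag.POSITIVE_CONSTANT:
        constant_value()
        positive_at_origin()
    elif tag is PropertyTag.SIGMOIDAL:
        nondecreasing(); zero_at_origin(); zero_slope_at_origin()
        finite_positive_limit(); derivative_unique_max()
    elif tag is PropertyTag.COMPLEMENTARY_SIGMOIDAL:
        nonincreasing(); positive_at_origin(); zero_slope_at_origin()
        null_limit(); derivative_unique_min()
    elif tag is PropertyTag.CONSTANT_SIGMOIDAL:
        nondecreasing(); positive_at_origin(); zero_slope_at_origin()
        finite_positive_limit(); derivative_unique_max()
    elif tag is PropertyTag.CONSTANT_COMPLEMENTARY_SIGMOIDAL:
        nonincreasing(); positive_at_origin(); zero_slope_at_origin()
        derivative_unique_min()
        if abs(y_far - y_end) > 1e-3 * max(abs(y0), tol):
            violated.append("f(inf) finite")
    elif tag is PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT:
        strictly_increasing(); finite_positive_limit(); derivative_decreasing()
    elif tag is PropertyTag.DECREASING_ASYMPTOTICALLY_NULL:
        strictly_decreasing_to("0"); null_limit(); derivative_increasing()
    elif tag is PropertyTag.DECREASING_EXACTLY_NULL:
        positive_at_origin(); nonincreasing(); exactly_null_tail()
        # strict decrease on the support {f > 0}
        support = y[:-1] > tol
        if np.any(diffs[support] >= -tol * 1e-3) and np.any(support):
            # allow the final blended points where f has just reached 0
            strict = diffs[support]
            if np.mean(strict >= 0) > 0.02:
                violated.append("f' < 0 below threshold")
    elif tag is PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED:
        strictly_increasing(); unbounded_growth()
    else:  # pragma: no cover - exhaustive
        raise ValueError(f"unknown tag {tag}")

    return PropertyReport(tag=tag, passed=not violated, violated=violated,
                          grid_max=float(grid_max))
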