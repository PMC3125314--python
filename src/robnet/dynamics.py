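"""Vector-field assembly, simulation and saturation-based state bounds.

The right-hand side of a concrete instance sums, per state ``i``::

    dx_i/dt = sum_j a_ij(.) x_j - sum_h b_ih(.) x_h + sum_s c_is(.) + sum_l d_il(.)

with modulator dependencies honored.  Inputs are bound as constants or as
functions of time.  Because every production term is nonnegative and every
degradation flux vanishes with its own state, the nonnegative orthant is
positively invariant; ``simulate`` enforces this numerically by failing a
run whose excursion below zero exceeds solver noise (10 * atol) and
clamping smaller excursions to zero on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .ensemble import ConcreteInstance
from .model import AffineArg, NetworkModel, Term
from .tags import PropertyTag

__all__ = [
    "VectorField",
    "Trajectory",
    "SolverError",
    "PositivityError",
    "assemble_rhs",
    "term_flux",
    "simulate",
    "invariant_box",
    "InvariantBox",
    "trajectory_to_csv",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
STEADY_TOL = 1e-9


class SolverError(RuntimeError):
    def __init__(self, msg, last_state=None):
        super().__init__(msg)
        self.last_state = last_state


class PositivityError(RuntimeError):
    """Trajectory left the nonnegative orthant beyond solver noise."""


def _resolve_arg(ref, constants):
    """Return a closure extracting the argument value from the full
    (states + inputs) vector; affine arguments are clipped at 0."""
    if ref is None:
        return lambda xa: 0.0
    if isinstance(ref, AffineArg):
        total = float(constants[ref.total])
        idx = tuple(ref.subtract)

        def get(xa, total=total, idx=idx):
            v = total
            for i in idx:
                v -= xa[i]
            return v if v > 0.0 else 0.0
        return get
    i = int(ref)
    return lambda xa, i=i: xa[i] if xa[i] > 0.0 else 0.0


def term_flux(term: Term, instance: ConcreteInstance, xa) -> float:
    """Signed flux of one term at a full variable vector (states+inputs)."""
    phi = instance.fn(term.name).as_scalar()
    get = _resolve_arg(term.arg, instance.constants)
    v = phi(get(xa)) if term.arg is not None else phi(0.0)
    for m, (mref, _) in zip(
            instance.modulator_assignments.get(term.name, ()), term.modulators):
        mget = _resolve_arg(mref, instance.constants)
        v *= m.as_scalar()(mget(xa))
    if term.kind in "ab" and not term.saturating_flux:
        v *= xa[term.mult]
    return v if term.kind in "acd" else -v


@dataclass
class VectorField:
    """Evaluable field ``(t, x) -> dx/dt`` for a concrete instance."""

    model: NetworkModel
    instance: ConcreteInstance
    input_values: dict = field(default_factory=dict)

    def __post_init__(self):
        m = self.model
        for name in m.input_names:
            if name not in self.input_values:
                raise ValueError(f"input {name!r} is not bound")
        self._inputs = [self.input_values[name] for name in m.input_names]
        self._time_varying = any(callable(v) for v in self._inputs)
        # precompile: (target, sign, phi, arg_getter, mult, [(mod, getter)])
        compiled = []
        for t in m.terms:
            phi = self.instance.fn(t.name).as_scalar()
            get = _resolve_arg(t.arg, self.instance.constants) \
                if t.arg is not None else None
            mods = [(mf.as_scalar(), _resolve_arg(mref, self.instance.constants))
                    for mf, (mref, _) in zip(
                        self.instance.modulator_assignments.get(t.name, ()),
                        t.modulators)]
            mult = t.mult if (t.kind in "ab" and not t.saturating_flux) else None
            sign = 1.0 if t.kind in "acd" else -1.0
            compiled.append((t.target, sign, phi, get, mult, mods))
        self._compiled = compiled

    @property
    def dimension(self) -> int:
        return self.model.n_states

    def _full(self, t, x):
        vals = [v(t) if callable(v) else v for v in self._inputs]
        return np.concatenate([x, np.asarray(vals, dtype=float)]) \
            if vals else x

    def __call__(self, t, x):
        x = np.asarray(x, dtype=float)
        xa = self._full(t, x)
        out = np.zeros(self.model.n_states)
        for target, sign, phi, get, mult, mods in self._compiled:
            v = phi(get(xa)) if get is not None else phi(0.0)
            for mphi, mget in mods:
                v *= mphi(mget(xa))
            if mult is not None:
                v *= xa[mult]
            out[target] += sign * v
        return out

    def eval_batch(self, X: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Vectorized evaluation over rows of ``X`` (m x n)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = X.shape[0]
        vals = [v(t) if callable(v) else v for v in self._inputs]
        XA = np.hstack([X, np.tile(np.asarray(vals, float), (m, 1))]) \
            if vals else X
        XAc = np.clip(XA, 0.0, None)
        out = np.zeros((m, self.model.n_states))
        consts = self.instance.constants
        for term in self.model.terms:
            phi = self.instance.fn(term.name)
            if term.arg is None:
                v = np.full(m, float(phi(0.0)))
            else:
                v = np.asarray(phi(self._batch_arg(term.arg, XAc, consts)))
            for mf, (mref, _) in zip(
                    self.instance.modulator_assignments.get(term.name, ()),
                    term.modulators):
                v = v * np.asarray(mf(self._batch_arg(mref, XAc, consts)))
            if term.kind in "ab" and not term.saturating_flux:
                v = v * XA[:, term.mult]
            out[:, term.target] += v if term.kind in "acd" else -v
        return out

    @staticmethod
    def _batch_arg(ref, XAc, consts):
        if isinstance(ref, AffineArg):
            v = float(consts[ref.total]) - XAc[:, list(ref.subtract)].sum(axis=1)
            return np.clip(v, 0.0, None)
        return XAc[:, int(ref)]

    def is_steady(self, x, t: float = 0.0, tol: float = STEADY_TOL) -> bool:
        f = self(t, np.asarray(x, dtype=float))
        return float(np.max(np.abs(f))) < tol * (1.0 + float(np.max(np.abs(x))))


def assemble_rhs(model: NetworkModel, instance: ConcreteInstance,
                 inputs: dict | None = None) -> VectorField:
    """Bind inputs and assemble the evaluable field of an instance."""
    inputs = dict(inputs or {})
    return VectorField(model=model, instance=instance, input_values=inputs)


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    steady: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def simulate(field: VectorField, x0, t_span=(0.0, 50.0),
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             t_eval=None, until_steady: bool = False,
             max_time: float = 1e5) -> Trajectory:
    """Adaptive stiff-capable integration (LSODA) with positivity checks.

    With ``until_steady`` the horizon is extended (doubling chunks up to
    ``max_time``) until the scale-free steadiness test
    ``||f(x)||_inf < 1e-9 (1 + ||x||_inf)`` passes.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("x0 must be componentwise nonnegative")

    ts_list, xs_list = [], []
    t0, t1 = float(t_span[0]), float(t_span[1])
    nfev = 0
    while True:
        sol = solve_ivp(field, (t0, t1), x0, method="LSODA",
                        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
        nfev += sol.nfev
        if not sol.success:
            raise SolverError(f"integration failed: {sol.message}",
                              last_state=sol.y[:, -1] if sol.y.size else x0)
        ts_list.append(sol.t)
        xs_list.append(sol.y.T)
        x0 = sol.y[:, -1].copy()
        t0 = sol.t[-1]
        if not until_steady or field.is_steady(x0, t0) or t0 >= max_time:
            break
        t1 = min(max_time, t0 + 2.0 * (t1 - t_span[0]))
        t_eval = None

    times = np.concatenate(ts_list)
    states = np.vstack(xs_list)
    floor = float(np.min(states))
    if floor < -10.0 * atol:
        raise PositivityError(
            f"state went to {floor:.3e}, below -10*atol = {-10 * atol:.1e}")
    states = np.clip(states, 0.0, None)
    steady = field.is_steady(states[-1], times[-1])
    return Trajectory(times=times, states=states, steady=steady,
                      diagnostics={"nfev": nfev, "rtol": rtol, "atol": atol,
                                   "min_raw": floor})


def trajectory_to_csv(traj: Trajectory, model: NetworkModel, path) -> None:
    header = "t," + ",".join(model.state_names)
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


# ---------------------------------------------------------------------------
# invariant box
# ---------------------------------------------------------------------------

@dataclass
class InvariantBox:
    """Componentwise upper bounds (possibly +inf) plus, when every state has
    a linear degradation floor and state-independent production ceilings, a
    bound on the total concentration: sum(x) <= sum_bound."""

    upper: np.ndarray
    sum_bound: float

    def finite(self, cap: float) -> np.ndarray:
        return np.where(np.isfinite(self.upper), self.upper, cap)


def _range_extrema(phi, lo: float, hi: float, n: int = 64):
    """(min, max) of a packaged scalar family over [lo, hi] (hi may be inf;
    limits are probed far beyond the characteristic scale)."""
    scale = phi.scale if hasattr(phi, "scale") else 1.0
    hi_eff = hi if np.isfinite(hi) else 1e12 * scale
    if hi_eff <= lo:
        hi_eff = lo + 1e-12
    grid = np.concatenate([[lo], np.geomspace(max(lo, 1e-9 * scale) + 1e-300,
                                              hi_eff, n)])
    y = np.asarray(phi(grid), dtype=float)
    return float(np.min(y)), float(np.max(y))


def invariant_box(model: NetworkModel, instance: ConcreteInstance,
                  inputs: dict | None = None) -> InvariantBox:
    """Saturation-argument state bounds, propagated through the dependency
    order: bounded production ceiling divided by the linear degradation
    floor, iterated to a fixed point; +inf where no bound is derivable."""
    input_vals = {}
    for k, v in (inputs or {}).items():
        input_vals[k] = float(v(0.0)) if callable(v) else float(v)
    n = model.n_states
    consts = instance.constants

    def arg_interval(ref, U):
        if ref is None:
            return (0.0, 0.0)
        if isinstance(ref, AffineArg):
            return (0.0, float(consts[ref.total]))
        i = int(ref)
        if i < n:
            return (0.0, U[i])
        name = model.var_name(i)
        u = input_vals.get(name, 0.0)
        return (u, u)

    def mult_sup(ref, U):
        if ref is None:
            return 1.0
        i = int(ref)
        if i < n:
            return U[i]
        return input_vals.get(model.var_name(i), 0.0)

    U = np.full(n, np.inf)
    for _ in range(n + 2):
        U_new = U.copy()
        for i in range(n):
            prod = 0.0
            beta = 0.0
            for t in model.terms_for(i):
                phi = instance.fn(t.name)
                lo_a, hi_a = arg_interval(t.arg, U)
                mods = [
                    _range_extrema(mf, *arg_interval(mref, U))
                    for mf, (mref, _) in zip(
                        instance.modulator_assignments.get(t.name, ()),
                        t.modulators)
                ]
                mod_min = float(np.prod([m[0] for m in mods])) if mods else 1.0
                mod_max = float(np.prod([m[1] for m in mods])) if mods else 1.0
                if t.kind in "cd":
                    unbounded = (t.tag == PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED
                                 and not np.isfinite(hi_a))
                    _, pmax = _range_extrema(phi, lo_a, hi_a)
                    prod += np.inf if unbounded else pmax * mod_max
                elif t.kind == "a":
                    ms = mult_sup(t.mult, U)
                    if not np.isfinite(ms):
                        prod = np.inf
                        continue
                    unbounded = (t.tag == PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED
                                 and not np.isfinite(hi_a))
                    _, cmax = _range_extrema(phi, lo_a, hi_a)
                    prod += np.inf if unbounded else cmax * mod_max * ms
                else:  # b
                    if not t.saturating_flux and t.mult == i:
                        cmin, _ = _range_extrema(phi, lo_a, hi_a)
                        beta += max(cmin, 0.0) * mod_min
            if beta > 0 and np.isfinite(prod):
                U_new[i] = min(U_new[i], prod / beta)
        if np.allclose(np.nan_to_num(U_new, posinf=1e300),
                       np.nan_to_num(U, posinf=1e300)):
            U = U_new
            break
        U = U_new

    # total-concentration bound: every state needs a constant degradation
    # floor and a state-free production ceiling (no 'a' term driven by a
    # state, no unbounded production)
    total_prod = 0.0
    min_beta = np.inf
    ok = True
    for i in range(n):
        beta = 0.0
        for t in model.terms_for(i):
            phi = instance.fn(t.name)
            if t.kind == "a" and t.mult is not None and t.mult < n:
                ok = False
                break
            if t.kind in "cd" or t.kind == "a":
                lo_a, hi_arg = arg_interval(t.arg, np.full(n, np.inf))
                _, pmax = _range_extrema(phi, lo_a, hi_arg)
                if t.tag == PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED \
                        and not np.isfinite(hi_arg):
                    ok = False
                    break
                for mf, (mref, _) in zip(
                        instance.modulator_assignments.get(t.name, ()),
                        t.modulators):
                    _, msup = _range_extrema(mf, *arg_interval(mref, np.full(n, np.inf)))
                    pmax *= msup
                mult = mult_sup(t.mult, np.full(n, np.inf)) if t.kind == "a" else 1.0
                total_prod += pmax * mult
            elif t.kind == "b" and not t.saturating_flux and t.mult == i:
                lo_a, hi_a = arg_interval(t.arg, np.full(n, np.inf))
                cmin, _ = _range_extrema(phi, lo_a, hi_a)
                beta += max(cmin, 0.0)
        if not ok:
            break
        if beta <= 0:
            ok = False
            break
        min_beta = min(min_beta, beta)
    sum_bound = total_prod / min_beta if ok and np.isfinite(total_prod) else np.inf
    return InvariantBox(upper=U, sum_bound=float(sum_bound))
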