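"""Sampling-based robustness certificates.

The analytic machinery being certified: a piecewise-linear (max-of-affine)
Lyapunov function decreases along trajectories iff the maximal directional
derivative over its active pieces is negative; a constraint set is
positively invariant iff the field never points outward across an active
constraint (Nagumo's condition); order-cone invariance around an
equilibrium implies monotone, overshoot-free convergence.  All three are
checked here by dense seeded sampling: a certificate is falsifiable
evidence at a configurable density, not a formal proof, and enlarging the
sample only ever worsens the reported margin (Halton points are a
deterministic prefix sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product

import numpy as np
from scipy.optimize import brentq
from scipy.stats import qmc

from .dynamics import Trajectory, VectorField

__all__ = [
    "PiecewiseLinearFunction",
    "LinearConstraint",
    "FunctionConstraint",
    "ConstraintSet",
    "CertificateReport",
    "decrease_certificate",
    "nagumo_certificate",
    "sector_certificate",
    "crossing_count",
    "decay_rate",
]

ACTIVE_TOL = 1e-9


@dataclass
class CertificateReport:
    holds: bool
    worst_margin: float
    witnesses: list = dc_field(default_factory=list)
    estimated_rate: float | None = None
    n_samples: int = 0
    seed: int | None = None
    notes: str = ""

    def __bool__(self) -> bool:
        return bool(self.holds)

    def to_dict(self) -> dict:
        return {
            "holds": bool(self.holds),
            "worst_margin": float(self.worst_margin),
            "witnesses": [np.asarray(w).tolist() for w in self.witnesses],
            "estimated_rate": (None if self.estimated_rate is None
                               else float(self.estimated_rate)),
            "n_samples": int(self.n_samples),
            "seed": self.seed,
            "notes": self.notes,
        }


@dataclass
class PiecewiseLinearFunction:
    """Max-of-affine function ``V(x) = max_k g_k . (x - center)``.

    The weighted 1-norm preset uses all ``+-w_i`` gradient combinations, so
    ``V(x) = sum_i w_i |x_i - center_i|``: for a two-species annihilation
    module this is the worst case between the total-concentration error and
    the concentration mismatch.
    """

    gradients: np.ndarray  # (p, n)
    center: np.ndarray

    @classmethod
    def weighted_one_norm(cls, center, weights=None) -> "PiecewiseLinearFunction":
        center = np.asarray(center, dtype=float)
        n = center.size
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("1-norm weights must be positive")
        G = np.array([[s * wi for s, wi in zip(signs, w)]
                      for signs in product((-1.0, 1.0), repeat=n)])
        return cls(gradients=G, center=center)

    def value(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.max((X - self.center) @ self.gradients.T, axis=1)

    def directional_derivative(self, X: np.ndarray, F: np.ndarray) -> np.ndarray:
        """Generalized Lyapunov derivative: max over active pieces of
        ``g . f``; the active set (pieces within ``ACTIVE_TOL*(1+V)`` of the
        max) is never empty."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = np.atleast_2d(np.asarray(F, dtype=float))
        vals = (X - self.center) @ self.gradients.T       # (m, p)
        V = np.max(vals, axis=1)
        act = vals >= (V - ACTIVE_TOL * (1.0 + np.abs(V)))[:, None]
        D = F @ self.gradients.T                          # (m, p)
        return np.max(np.where(act, D, -np.inf), axis=1)

    def positive_definite_on(self, X: np.ndarray, tol: float = 1e-12) -> bool:
        V = self.value(X)
        d = np.max(np.abs(np.atleast_2d(X) - self.center), axis=1)
        return bool(np.all(V[d > tol] > 0))


# ---------------------------------------------------------------------------
# constraint sets
# ---------------------------------------------------------------------------

@dataclass
class LinearConstraint:
    """``w . x <= sigma``."""

    w: np.ndarray
    sigma: float
    label: str = ""

    def s(self, X):
        return np.atleast_2d(np.asarray(X, float)) @ np.asarray(self.w, float)

    def grad(self, x):
        return np.asarray(self.w, dtype=float)

    def project(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w = np.asarray(self.w, dtype=float)
        lam = (self.sigma - X @ w) / (w @ w)
        return X + lam[:, None] * w


@dataclass
class FunctionConstraint:
    """``s(x) <= sigma`` for a smooth scalar ``s`` with finite-difference
    gradient; the boundary is reached by a bracketed line search."""

    s_func: object
    sigma: float
    label: str = ""

    def s(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([float(self.s_func(x)) for x in X])

    def grad(self, x, h: float = 1e-6):
        x = np.asarray(x, dtype=float)
        g = np.empty(x.size)
        for j in range(x.size):
            hp = h * (1.0 + abs(x[j]))
            xp = x.copy(); xp[j] += hp
            xm = x.copy(); xm[j] -= hp
            g[j] = (float(self.s_func(xp)) - float(self.s_func(xm))) / (2 * hp)
        return g

    def project(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for x in X:
            g = self.grad(x)
            ng = np.linalg.norm(g)
            if ng == 0:
                continue
            g = g / ng

            def line(t):
                return float(self.s_func(x + t * g)) - self.sigma

            t_hi, t_lo = 1.0, -1.0
            bracket = None
            for _ in range(40):
                if line(t_lo) * line(t_hi) <= 0:
                    bracket = (t_lo, t_hi)
                    break
                t_lo *= 2.0
                t_hi *= 2.0
            if bracket is None:
                continue
            t = brentq(line, *bracket, xtol=1e-12)
            out.append(x + t * g)
        return np.asarray(out) if out else np.empty((0, X.shape[1]))


@dataclass
class ConstraintSet:
    constraints: list
    description: str = ""


class ProjectionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# certificates
# ---------------------------------------------------------------------------

def _halton(n, dim, seed):
    return qmc.Halton(d=dim, scramble=True, seed=seed).random(n)


def _field_scale(F: np.ndarray) -> float:
    m = float(np.median(np.max(np.abs(np.atleast_2d(F)), axis=1)))
    return max(m, 1e-12)


def decrease_certificate(field: VectorField, V: PiecewiseLinearFunction,
                         region, exclusion_radius: float | None = None,
                         n_samples: int = 20000, seed: int = 0,
                         center_tol: float = 1e-6) -> CertificateReport:
    """Generalized-derivative decrease check on a box minus a small ball
    around the center.  Holds iff the derivative is negative at every
    sample; the estimated exponential rate is the worst sampled ratio
    ``-dV/V`` (the linear comparison function)."""
    lo, hi = _region_bounds(region, field.dimension)
    c = V.center
    fc = np.asarray(field(0.0, c))
    if np.max(np.abs(fc)) > center_tol * (1.0 + np.max(np.abs(c))):
        raise ValueError("certificate center is not an equilibrium "
                         f"(||f|| = {np.max(np.abs(fc)):.2e})")
    if exclusion_radius is None:
        exclusion_radius = 1e-3 * float(np.max(hi - lo))
    X = lo + _halton(n_samples, c.size, seed) * (hi - lo)
    keep = np.linalg.norm(X - c, axis=1) > exclusion_radius
    X = X[keep]
    F = field.eval_batch(X)
    Vv = V.value(X)
    D = V.directional_derivative(X, F)
    fscale = _field_scale(F)
    worst = float(np.max(D))
    holds = worst <= 1e-10 * fscale
    ratios = -D / np.maximum(Vv, 1e-300)
    rate = float(np.min(ratios)) if holds else float(np.min(ratios))
    iw = int(np.argmax(D))
    return CertificateReport(holds=holds, worst_margin=worst,
                             witnesses=[X[iw]], estimated_rate=max(rate, 0.0),
                             n_samples=int(X.shape[0]), seed=seed)


def _region_bounds(region, dim):
    region = np.asarray(region, dtype=float)
    if region.ndim == 1:
        return np.zeros(dim), region
    return region[0], region[1]


def nagumo_certificate(field: VectorField, cset: ConstraintSet, region,
                       n_boundary: int = 2000, seed: int = 0,
                       slack_rel: float = 1e-8) -> CertificateReport:
    """Boundary check of Nagumo's invariance condition for
    ``{x : s_i(x) <= sigma_i for all i}``: on sampled points of each active
    constraint boundary (feasible for the others), the outward derivative
    ``grad s_i . f`` must not be positive."""
    lo, hi = _region_bounds(region, field.dimension)
    worst = -np.inf
    witness = None
    total = 0
    rng_shift = 0
    for ci, con in enumerate(cset.constraints):
        X = lo + _halton(n_boundary, field.dimension, seed + rng_shift) * (hi - lo)
        rng_shift += 1
        B = con.project(X)
        if B.size == 0:
            raise ProjectionError(
                f"cannot reach boundary of constraint {ci} "
                f"({con.label or 'unlabeled'})")
        # keep points feasible for the other constraints
        feas = np.ones(B.shape[0], dtype=bool)
        for cj, other in enumerate(cset.constraints):
            if cj == ci:
                continue
            sj = other.s(B)
            feas &= sj <= other.sigma + 1e-9 * (1.0 + np.abs(other.sigma))
        B = B[feas]
        if B.size == 0:
            continue
        F = field.eval_batch(B)
        margins = np.array([float(np.dot(con.grad(b), f))
                            for b, f in zip(B, F)])
        total += B.shape[0]
        i = int(np.argmax(margins))
        if margins[i] > worst:
            worst = float(margins[i])
            witness = B[i]
    fscale = _field_scale(field.eval_batch((lo + hi) / 2.0))
    holds = worst <= slack_rel * fscale
    return CertificateReport(holds=holds, worst_margin=worst,
                             witnesses=[witness] if witness is not None else [],
                             n_samples=total, seed=seed)


def sector_certificate(field: VectorField, x_star, sign_pattern, box,
                       n_boundary: int = 2000, seed: int = 0,
                       center_tol: float = 1e-6,
                       slack_rel: float = 1e-8) -> CertificateReport:
    """Invariance of the order sector through an equilibrium.

    ``sign_pattern`` gives per state ``'>='`` (sector above the equilibrium
    in that coordinate) or ``'<='``.  On each face ``x_i = x_i*`` (the other
    coordinates sampled inside the sector and the box) the field must not
    point out of the sector: ``-+ f_i <= 0``.  A passing certificate rules
    out over/undershoot of that coordinate inside the sector.
    """
    x_star = np.asarray(x_star, dtype=float)
    fc = np.asarray(field(0.0, x_star))
    if np.max(np.abs(fc)) > center_tol * (1.0 + np.max(np.abs(x_star))):
        raise ValueError("sector apex is not an equilibrium")
    lo, hi = _region_bounds(box, field.dimension)
    n = x_star.size
    sector_lo = np.where([p == ">=" for p in sign_pattern], x_star, lo)
    sector_hi = np.where([p == ">=" for p in sign_pattern], hi, x_star)
    worst = -np.inf
    witness = None
    total = 0
    for i, pat in enumerate(sign_pattern):
        U = _halton(n_boundary, n, seed + i)
        B = sector_lo + U * (sector_hi - sector_lo)
        B[:, i] = x_star[i]
        F = field.eval_batch(B)
        margins = -F[:, i] if pat == ">=" else F[:, i]
        total += B.shape[0]
        k = int(np.argmax(margins))
        if margins[k] > worst:
            worst = float(margins[k])
            witness = B[k]
    fscale = _field_scale(field.eval_batch((sector_lo + sector_hi) / 2.0))
    holds = worst <= slack_rel * max(fscale, float(np.max(np.abs(fc))) * 10)
    return CertificateReport(holds=holds, worst_margin=worst,
                             witnesses=[witness] if witness is not None else [],
                             n_samples=total, seed=seed)


def crossing_count(trajectory: Trajectory, x_star, dead_band: float = 1e-6):
    """Per-state number of sign changes of ``x_i(t) - x_i*`` outside a dead
    band.  A monotone-approach claim means each count is at most one."""
    x_star = np.asarray(x_star, dtype=float)
    Y = trajectory.states - x_star
    counts = np.zeros(x_star.size, dtype=int)
    for i in range(x_star.size):
        band = dead_band * (1.0 + abs(x_star[i]))
        s = np.where(Y[:, i] > band, 1, np.where(Y[:, i] < -band, -1, 0))
        s = s[s != 0]
        if s.size:
            counts[i] = int(np.sum(np.diff(s) != 0))
    return counts


def decay_rate(times, V_series, floor_rel: float = 1e-8):
    """Exponential rate fitted to ``log V`` over the window ``V > 1e-8 V(0)``.

    Returns ``(rate, warning)``; the warning flags non-monotone decay
    beyond tolerance (the decrease certificate has likely failed).
    """
    t = np.asarray(times, dtype=float)
    V = np.asarray(V_series, dtype=float)
    if V.size == 0 or V[0] <= 0:
        return 0.0, "empty or nonpositive V series"
    mask = V > floor_rel * V[0]
    warning = ""
    tm, Vm = t[mask], V[mask]
    if np.any(np.diff(Vm) > 1e-6 * np.maximum(Vm[:-1], 1e-300)):
        warning = "V is not monotonically decreasing"
    if tm.size < 3 or tm[-1] <= tm[0]:
        return 0.0, warning or "window too short"
    span = np.ptp(np.log(Vm))
    if span < 1e-12:
        return 0.0, warning
    slope = np.polyfit(tm, np.log(Vm), 1)[0]
    return float(max(-slope, 0.0)), warning
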