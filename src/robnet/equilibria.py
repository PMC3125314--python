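"""Equilibrium finding, stability classification and ordering checks.

Equilibria are located by multistart root finding (Powell hybrid) from
low-discrepancy (Halton) starts inside the invariant box, polished,
deduplicated within a merge radius and sorted by first coordinate.
Stability is read off the eigenvalues of a central-difference Jacobian with
a marginality dead band: propositions about equilibrium counts assume
simple equilibria, so near-marginal ones are reported, not classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .dynamics import VectorField

__all__ = [
    "Equilibrium",
    "ResponseCurve",
    "find_equilibria",
    "classify",
    "jacobian_fd",
    "check_order",
    "response_curve",
]

MARGIN = 1e-6  # dead band on Re(lambda) for marginality


@dataclass
class Equilibrium:
    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray | None = None
    classification: str = "unclassified"  # stable | unstable | marginal

    @property
    def stable(self) -> bool:
        return self.classification == "stable"


def _residual_tol(x: np.ndarray, tol: float) -> float:
    return tol * (1.0 + float(np.max(np.abs(x))))


def find_equilibria(field: VectorField, box, n_starts: int = 200,
                    seed: int = 0, merge_radius: float = 1e-6,
                    tol: float = 1e-9, classify_roots: bool = True,
                    t: float = 0.0, extra_starts=None) -> list[Equilibrium]:
    """All distinct roots of the field found from ``n_starts`` Halton starts
    in ``[0, box]``; empty list when nothing converges (a legitimate
    outcome: strong unbounded feedback removes all equilibria).

    ``extra_starts`` prepends informed starts (e.g. from a semi-analytic
    reduction) to the quasi-random ones; every accepted root is polished
    and residual-checked regardless of provenance."""
    box = np.asarray(box, dtype=float)
    n = field.dimension
    scale = float(np.max(box))
    sampler = qmc.Halton(d=n, scramble=True, seed=seed)
    starts = sampler.random(n_starts) * box
    if extra_starts is not None and len(extra_starts):
        extra = np.clip(np.atleast_2d(np.asarray(extra_starts, float)),
                        0.0, box)
        starts = np.vstack([extra, starts])

    def fun(x):
        return field(t, x)

    found: list[np.ndarray] = []
    radius = merge_radius * max(scale, 1.0)
    lo_bounds = np.zeros(n)
    for x0 in starts:
        # fast Newton first; if it diverges or leaves the box, retry with
        # bounded trust-region least squares (the assembled fields are only
        # meaningful on the nonnegative orthant and may be flat outside
        # conserved-pool simplices, which strands Newton iterations)
        sol = optimize.root(fun, x0, method="hybr", tol=1e-12)
        x = sol.x
        in_box = np.all(x > -radius) and np.all(x < box + radius)
        if not (sol.success and in_box):
            ls = optimize.least_squares(fun, x0, bounds=(lo_bounds, box),
                                        method="trf", xtol=1e-12, ftol=1e-14,
                                        gtol=None, max_nfev=400)
            x = ls.x
            # Newton polish from the box solution, kept only if it improves
            sol2 = optimize.root(fun, np.clip(x, 0.0, None),
                                 method="hybr", tol=1e-14)
            x2 = sol2.x
            if np.all(x2 > -radius) and np.all(x2 < box + radius) \
                    and np.max(np.abs(fun(np.clip(x2, 0.0, None)))) \
                    <= np.max(np.abs(fun(np.clip(x, 0.0, None)))):
                x = x2
        x = np.clip(x, 0.0, None)
        if np.any(x > box * (1.0 + 1e-6) + radius):
            continue
        res = float(np.max(np.abs(fun(x))))
        if res > _residual_tol(x, tol):
            continue
        if any(np.max(np.abs(x - y)) < radius for y in found):
            continue
        found.append(x)

    found.sort(key=lambda v: tuple(v))
    eqs = []
    for x in found:
        res = float(np.max(np.abs(fun(x))))
        if classify_roots:
            eqs.append(classify(field, x, tol=tol))
        else:
            eqs.append(Equilibrium(state=x, residual=res))
    return eqs


def jacobian_fd(field: VectorField, x: np.ndarray, fd_step: float | None = None,
                t: float = 0.0) -> np.ndarray:
    """Central-difference Jacobian, step ~ sqrt(eps) * (1 + |x_j|)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = fd_step if fd_step else np.sqrt(np.finfo(float).eps) * (1.0 + abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (field(t, xp) - field(t, xm)) / (xp[j] - xm[j])
    return J


def classify(field: VectorField, x_star, fd_step: float | None = None,
             tol: float = 1e-8, t: float = 0.0) -> Equilibrium:
    """Eigenvalue classification with marginality dead band ``1e-6``."""
    x_star = np.asarray(x_star, dtype=float)
    res = float(np.max(np.abs(field(t, x_star))))
    if res > _residual_tol(x_star, max(tol, 1e-7)):
        raise ValueError(f"not an equilibrium: residual {res:.3e}")
    J = jacobian_fd(field, x_star, fd_step, t)
    eig = np.linalg.eigvals(J)
    re = np.real(eig)
    if np.all(re < -MARGIN):
        cls = "stable"
    elif np.any(re > MARGIN):
        cls = "unstable"
    else:
        cls = "marginal"
    return Equilibrium(state=x_star, residual=res, eigenvalues=eig,
                       classification=cls)


def check_order(equilibria: list[Equilibrium], subset=None,
                directions: dict | None = None, rtol: float = 1e-6):
    """Componentwise total order over ``subset`` coordinates.

    Returns ``(ordered, permutation)`` where the permutation sorts the
    equilibria along the order.  ``directions`` maps a coordinate to ``-1``
    when it is expected reverse-ordered (the partial order of cascade
    models with conserved pools: phosphorylated forms up, unphosphorylated
    forms down along the same branch ordering).
    """
    if len(equilibria) < 2:
        return True, tuple(range(len(equilibria)))
    X = np.stack([np.asarray(e.state, dtype=float) for e in equilibria])
    n = X.shape[1]
    subset = list(range(n)) if subset is None else list(subset)
    directions = directions or {}
    signs = np.array([directions.get(i, 1) for i in subset], dtype=float)
    Y = X[:, subset] * signs
    perm = tuple(int(i) for i in np.argsort(Y[:, 0], kind="stable"))
    Ys = Y[list(perm)]
    scale = np.maximum(np.max(np.abs(Y), axis=0), 1.0)
    ordered = bool(np.all(np.diff(Ys, axis=0) >= -rtol * scale))
    return ordered, perm


@dataclass
class ResponseCurve:
    """Equilibria tracked along an input grid by nearest-neighbor matching."""

    grid: np.ndarray
    points: list  # per grid value: list[Equilibrium]
    branches: list = field(default_factory=list)  # list of (idx array, states)
    folds: list = field(default_factory=list)     # grid indices where count changes

    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.points])

    def monotonicity(self, branch: int) -> np.ndarray:
        """Per-state flag: +1 nondecreasing, -1 nonincreasing, 0 neither."""
        idx, states = self.branches[branch]
        d = np.diff(states, axis=0)
        scale = np.maximum(np.max(np.abs(states), axis=0), 1e-12)
        out = np.zeros(states.shape[1], dtype=int)
        for j in range(states.shape[1]):
            tolj = 1e-7 * scale[j]
            if np.all(d[:, j] >= -tolj):
                out[j] = 1
            elif np.all(d[:, j] <= tolj):
                out[j] = -1
        return out


def response_curve(model, instance, input_id: str, grid,
                   base_inputs: dict | None = None, box=None,
                   n_starts: int = 120, seed: int = 0,
                   merge_radius: float = 1e-6,
                   box_cap: float = 100.0) -> ResponseCurve:
    """Steady-state response: equilibria per input value with branch
    matching and fold markers where the branch count changes."""
    from .dynamics import assemble_rhs, invariant_box

    grid = np.asarray(grid, dtype=float)
    pts = []
    for k, u in enumerate(grid):
        inputs = dict(base_inputs or {})
        inputs[input_id] = float(u)
        f = assemble_rhs(model, instance, inputs)
        if box is None:
            b = invariant_box(model, instance, inputs).finite(box_cap)
        else:
            b = np.asarray(box, dtype=float)
        pts.append(find_equilibria(f, b, n_starts=n_starts, seed=seed + k,
                                   merge_radius=merge_radius))

    folds = [k for k in range(1, len(pts)) if len(pts[k]) != len(pts[k - 1])]

    # greedy nearest-neighbor chaining into branches
    branches: list[list[tuple[int, np.ndarray]]] = []
    open_branches: list[list[tuple[int, np.ndarray]]] = []
    for k, eqs in enumerate(pts):
        states = [np.asarray(e.state) for e in eqs]
        used = [False] * len(states)
        still_open = []
        for br in open_branches:
            last = br[-1][1]
            best, bestd = None, np.inf
            for i, s in enumerate(states):
                if used[i]:
                    continue
                d = float(np.max(np.abs(s - last)))
                if d < bestd:
                    best, bestd = i, d
            if best is not None and bestd < 0.5 * (1.0 + float(np.max(np.abs(last)))):
                br.append((k, states[best]))
                used[best] = True
                still_open.append(br)
            else:
                branches.append(br)
        open_branches = still_open
        for i, s in enumerate(states):
            if not used[i]:
                open_branches.append([(k, s)])
    branches.extend(open_branches)

    packed = [(np.array([k for k, _ in br]),
               np.stack([s for _, s in br])) for br in branches if br]
    return ResponseCurve(grid=grid, points=pts, branches=packed, folds=folds)
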