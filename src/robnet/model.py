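"""Qualitative network models built from property-tagged interaction terms.

A model is a list of typed terms over states and inputs.  Each term
contributes one flux to the ODE right-hand side of its target state:

==========  =============================================  ==================
kind        flux                                           meaning
==========  =============================================  ==================
``a``       ``+ phi(arg) * x[mult] * prod(mods)``          production driven
                                                           linearly by a
                                                           source species
``b``       ``- phi(arg) * x[mult] * prod(mods)``          degradation or
                                                           conversion
``b`` flux  ``- phi(arg) * prod(mods)``                    saturating
(``saturating_flux``)                                      degradation flux
``c``       ``+ phi(arg) * prod(mods)``                    saturating
                                                           production
``d``       ``+ phi(arg) * prod(mods)``                    decreasing
                                                           saturating
                                                           production
==========  =============================================  ==================

``phi`` is the term's tagged function, assigned only when the model is
instantiated (:mod:`robnet.ensemble`).  Inputs are modeled as constant
pseudo-states appended after the states, so ``arg``/``mult`` may refer to
either.  An argument may also be an affine expression ``total - sum(states)``
(:class:`AffineArg`), which is how conserved totals enter reduced models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import networkx as nx
import numpy as np

from .tags import (
    NON_DECREASING_TAGS,
    NON_INCREASING_TAGS,
    VANISHING_AT_ZERO_TAGS,
    PropertyTag,
)

__all__ = [
    "AffineArg",
    "Term",
    "NetworkModel",
    "ConservedSum",
    "StructuralError",
    "ValidationReport",
    "validate_model",
    "build_graph",
    "export_graph_csv",
    "detect_conserved_sums",
]


class StructuralError(ValueError):
    """Malformed model structure (bad index, missing field) -- distinct
    from a violated modeling assumption, which is reported, not raised."""


@dataclass(frozen=True)
class AffineArg:
    """Argument of the form ``constants[total] - sum(x[i] for i in subtract)``."""

    total: str
    subtract: tuple[int, ...]


@dataclass(frozen=True)
class Term:
    """One property-tagged flux contribution to a single state."""

    name: str
    target: int
    kind: str  # 'a' | 'b' | 'c' | 'd'
    tag: PropertyTag
    arg: int | AffineArg | None = None
    mult: int | None = None
    modulators: tuple[tuple[int | AffineArg, PropertyTag], ...] = ()
    saturating_flux: bool = False
    coupling_id: str | None = None
    family: str | None = None
    a5_flag: bool = False


@dataclass(frozen=True)
class NetworkModel:
    """A qualitative model: states, inputs and tagged terms."""

    state_names: tuple[str, ...]
    input_names: tuple[str, ...] = ()
    terms: tuple[Term, ...] = ()
    notes: str = ""
    name: str = ""

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_vars(self) -> int:
        """States plus inputs-as-pseudo-states."""
        return self.n_states + self.n_inputs

    def index(self, name: str) -> int:
        """Index of a state or input by name (inputs follow states)."""
        if name in self.state_names:
            return self.state_names.index(name)
        if name in self.input_names:
            return self.n_states + self.input_names.index(name)
        raise StructuralError(f"unknown state/input {name!r}")

    def var_name(self, idx: int) -> str:
        if 0 <= idx < self.n_states:
            return self.state_names[idx]
        if self.n_states <= idx < self.n_vars:
            return self.input_names[idx - self.n_states]
        raise StructuralError(f"index {idx} out of range")

    def terms_for(self, state: int) -> list[Term]:
        return [t for t in self.terms if t.target == state]


@dataclass(frozen=True)
class ConservedSum:
    """Integer weight vector w with w . f(x) ~ 0 at all sampled states."""

    weights: tuple[int, ...]
    tolerance: float
    value_expression: str = "sum of initial conditions"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    passed: bool
    diagnostics: list[dict] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def _check_ref(model: NetworkModel, ref, term: Term, what: str) -> None:
    if ref is None:
        return
    if isinstance(ref, AffineArg):
        for i in ref.subtract:
            if not (0 <= i < model.n_states):
                raise StructuralError(
                    f"term {term.name!r}: affine {what} refers to state "
                    f"index {i} out of range")
        return
    if not (0 <= ref < model.n_vars):
        raise StructuralError(
            f"term {term.name!r}: {what} index {ref} out of range")


def validate_model(model: NetworkModel) -> ValidationReport:
    """Check every term's (kind, tag) pair against the modeling assumptions.

    Structural problems (out-of-range indices, missing multiplier on an
    ``a``/``b`` term) raise :class:`StructuralError`.  Assumption violations
    are collected in the report, one diagnostic per violation, naming the
    assumption: A4 constrains the monotonicity class of ``c``/``d`` terms,
    A5 requires conversion coefficients to vanish at the target's lower
    saturation level.  Idempotent and side-effect free.
    """
    diags: list[dict] = []

    seen_targets = set()
    couplings: dict[str, Term] = {}
    for t in model.terms:
        if t.kind not in "abcd":
            raise StructuralError(f"term {t.name!r}: unknown kind {t.kind!r}")
        if not (0 <= t.target < model.n_states):
            raise StructuralError(
                f"term {t.name!r}: target index {t.target} out of range")
        _check_ref(model, t.arg, t, "arg")
        _check_ref(model, t.mult, t, "mult")
        for m, _ in t.modulators:
            _check_ref(model, m, t, "modulator")
        if t.kind in "ab" and t.mult is None and not t.saturating_flux:
            raise StructuralError(
                f"term {t.name!r}: kind {t.kind!r} requires a multiplied "
                "state or input")
        if t.saturating_flux and t.kind != "b":
            raise StructuralError(
                f"term {t.name!r}: saturating_flux only applies to kind 'b'")
        seen_targets.add(t.target)

        tag = PropertyTag(t.tag)
        degenerate_ok = tag is PropertyTag.NONNEGATIVE_CONSTANT
        if t.kind == "c" and tag not in NON_DECREASING_TAGS \
                and not degenerate_ok:
            diags.append({"term": t.name, "assumption": "A4",
                          "message": f"c-term tagged {tag} is not in the "
                                     "non-decreasing class"})
        if t.kind == "d" and tag not in NON_INCREASING_TAGS \
                and not degenerate_ok:
            diags.append({"term": t.name, "assumption": "A4",
                          "message": f"d-term tagged {tag} is not in the "
                                     "non-increasing class"})
        if t.kind == "b":
            off_target = (not t.saturating_flux
                          and t.mult != t.target
                          and t.mult is not None
                          and t.mult < model.n_states)
            if off_target:
                coeff_on_target = t.arg == t.target
                if not (coeff_on_target and tag in VANISHING_AT_ZERO_TAGS) \
                        and not t.a5_flag:
                    diags.append({
                        "term": t.name, "assumption": "A5",
                        "message": "conversion coefficient must vanish when "
                                   f"{model.var_name(t.target)} = 0 (tag the "
                                   "coefficient on the target with a "
                                   "vanishing-at-zero class or set a5_flag)"})
            if t.saturating_flux:
                if t.arg != t.target:
                    diags.append({
                        "term": t.name, "assumption": "A5",
                        "message": "saturating degradation flux must read "
                                   "its own target"})
                if tag not in VANISHING_AT_ZERO_TAGS:
                    diags.append({
                        "term": t.name, "assumption": "A5",
                        "message": f"saturating flux tagged {tag} cannot "
                                   "vanish at 0"})
        if t.coupling_id is not None:
            other = couplings.setdefault(t.coupling_id, t)
            if other is not t and PropertyTag(other.tag) != tag:
                diags.append({
                    "term": t.name, "assumption": "coupling",
                    "message": f"coupled terms {other.name!r}/{t.name!r} "
                               "carry different tags"})

    for i in range(model.n_states):
        if i not in seen_targets:
            diags.append({"term": None, "assumption": "structure",
                          "message": f"state {model.state_names[i]!r} has "
                                     "no terms"})

    return ValidationReport(passed=not diags, diagnostics=diags)


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------

def build_graph(model: NetworkModel) -> nx.MultiDiGraph:
    """Typed interaction graph: species and input nodes, one arc per term,
    dashed arcs for modulation of a/b coefficients."""
    g = nx.MultiDiGraph(name=model.name)
    for s in model.state_names:
        g.add_node(s, node_class="species")
    for u in model.input_names:
        g.add_node(u, node_class="input")

    def ref_name(ref):
        if ref is None or isinstance(ref, AffineArg):
            return None
        return model.var_name(ref)

    for t in model.terms:
        tgt = model.state_names[t.target]
        if t.kind in "cd":
            src = ref_name(t.arg)
            if src is not None:
                g.add_edge(src, tgt, kind=t.kind, term=t.name, dashed=False)
        else:  # a / b
            mult = ref_name(t.mult)
            if t.kind == "b" and t.saturating_flux:
                src = tgt
            elif t.kind == "b" and mult == tgt and ref_name(t.arg) not in (None, tgt):
                src = ref_name(t.arg)  # e.g. input-modulated degradation
            else:
                src = mult
            if src is not None:
                g.add_edge(src, tgt, kind=t.kind, term=t.name, dashed=False)
            coeff = ref_name(t.arg)
            if coeff is not None and coeff not in (src, tgt):
                g.add_edge(coeff, tgt, kind=t.kind, term=t.name, dashed=True)
        for m, _ in t.modulators:
            mname = ref_name(m)
            if mname is not None:
                g.add_edge(mname, tgt, kind=t.kind, term=t.name, dashed=True)
    return g


def export_graph_csv(graph: nx.MultiDiGraph, path) -> None:
    """Edge list as ``source, target, kind, dashed`` (RFC-4180)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "kind", "dashed"])
        for u, v, data in graph.edges(data=True):
            w.writerow([u, v, data.get("kind", ""),
                        int(bool(data.get("dashed", False)))])


# ---------------------------------------------------------------------------
# conserved sums
# ---------------------------------------------------------------------------

def _rref(mat: np.ndarray, tol: float) -> np.ndarray:
    """Reduced row echelon form with partial pivoting (float, tolerant)."""
    a = mat.astype(float).copy()
    rows, cols = a.shape
    r = 0
    for c in range(cols):
        if r >= rows:
            break
        piv = r + int(np.argmax(np.abs(a[r:, c])))
        if abs(a[piv, c]) < tol:
            continue
        a[[r, piv]] = a[[piv, r]]
        a[r] /= a[r, c]
        for i in range(rows):
            if i != r and abs(a[i, c]) > 0:
                a[i] -= a[i, c] * a[r]
        r += 1
    return a[:r]


def _rationalize(w: np.ndarray, max_den: int = 12) -> tuple[int, ...] | None:
    scale = np.max(np.abs(w))
    if scale == 0:
        return None
    fracs = [Fraction(float(v / scale)).limit_denominator(max_den) for v in w]
    den = 1
    for f in fracs:
        den = den * f.denominator // gcd(den, f.denominator)
    ints = [int(f * den) for f in fracs]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g == 0:
        return None
    ints = [v // g for v in ints]
    lead = next(v for v in ints if v != 0)
    if lead < 0:
        ints = [-v for v in ints]
    return tuple(ints)


def detect_conserved_sums(model: NetworkModel, instance, n_samples: int = 0,
                          seed: int = 0, tolerance: float = 1e-8,
                          box_scale: float = 5.0) -> list[ConservedSum]:
    """Find small-integer weight vectors ``w`` with ``w . f(x) ~ 0``.

    Samples random states, stacks right-hand-side vectors, takes the
    numerical left null space (SVD), reduces the basis to row echelon form
    so moiety-type generators come out sparse, and rationalizes the weights
    with denominator <= 12.  The result is invariant to the sampling seed
    for ``n_samples >= 2 * n_states`` (up to sign and scale).
    """
    from .dynamics import assemble_rhs, invariant_box

    n = model.n_states
    if n_samples <= 0:
        n_samples = max(3 * n, 12)
    field_ = assemble_rhs(model, instance)
    box = invariant_box(model, instance)
    hi = np.where(np.isfinite(box.upper), box.upper, box_scale)
    hi = np.maximum(hi, 1e-6)
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_samples, n)) * hi
    F = np.stack([np.asarray(field_(0.0, x)) for x in X])

    norms = np.linalg.norm(F, axis=1)
    if np.all(norms < 1e-14):
        return [ConservedSum(weights=tuple(int(v) for v in e), tolerance=tolerance)
                for e in np.eye(n, dtype=int)]

    _, s, vt = np.linalg.svd(F)
    smax = s[0] if len(s) else 1.0
    null_rows = vt[len(s):].tolist() if F.shape[1] > len(s) else []
    null_rows += [vt[i] for i in range(len(s)) if s[i] <= 1e-10 * max(smax, 1.0)]
    if not null_rows:
        return []
    basis = _rref(np.asarray(null_rows), tol=1e-8)

    out: list[ConservedSum] = []
    for row in basis:
        ints = _rationalize(row)
        if ints is None:
            continue
        w = np.asarray(ints, dtype=float)
        resid = np.abs(F @ w)
        if np.all(resid <= tolerance * np.maximum(norms, 1.0) * np.linalg.norm(w)):
            out.append(ConservedSum(weights=ints, tolerance=tolerance))
    return out
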