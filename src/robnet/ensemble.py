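"""Random concrete instantiation of qualitative models.

A qualitative model only fixes tags; the family of concrete systems it
stands for is realized computationally by seeded sampling: every term gets
a parametric function of the right shape class, with parameters drawn
log-uniformly over decades (rates, half-saturations, amplitudes) and
integer-uniformly for Hill exponents.  A robustness claim is then checked
against an ensemble of such instances: it holds robustly if it holds for
every member.

Sub-seeds for ensemble members are derived with ``numpy``'s
``SeedSequence.spawn`` (counter-based splitting), so adding draws inside
one instance never perturbs any other instance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .functions import (
    TAG_DEFAULT_FAMILY,
    ParametricFunction,
    make_function,
    verify_property,
)
from .model import NetworkModel, validate_model
from .tags import PropertyTag

__all__ = [
    "SamplingConfig",
    "ConcreteInstance",
    "ConfigurationError",
    "sample_instance",
    "generate_ensemble",
    "check_a5",
]


class ConfigurationError(ValueError):
    pass


#: parameters drawn log-uniformly, by name
_LOG_PARAMS = ("value", "amplitude", "K", "slope", "theta", "base")


@dataclass(frozen=True)
class SamplingConfig:
    """Per-role log-uniform ranges; Hill exponents integer-uniform.

    ``ranges`` maps parameter names to ``(low, high)`` decades.  ``hill``
    is the inclusive integer range for Hill exponents of the sigmoid
    classes (minimum 2, so the zero-initial-slope requirement holds).
    ``term_params`` pins or re-ranges parameters of individual terms:
    ``{term_name: {param: value | (low, high)}}``.  ``constants`` supplies
    conserved totals referenced by affine arguments.
    """

    ranges: dict = field(default_factory=dict)
    hill: tuple[int, int] = (2, 4)
    term_params: dict = field(default_factory=dict)
    modulator_params: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)

    DEFAULT_RANGE = (1e-2, 1e2)

    def range_for(self, param: str) -> tuple[float, float]:
        lo, hi = self.ranges.get(param, self.DEFAULT_RANGE)
        return float(lo), float(hi)


def _draw_params(family: str, tag: PropertyTag, rng: np.random.Generator,
                 config: SamplingConfig, overrides: dict) -> dict:
    from .functions import FAMILY_DEFAULTS

    params = {}
    for name in FAMILY_DEFAULTS[family]:
        if name in overrides:
            spec = overrides[name]
            if isinstance(spec, (tuple, list)):
                lo, hi = float(spec[0]), float(spec[1])
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[name] = float(spec)
        elif name == "H":
            lo, hi = config.hill
            if tag in (PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT,
                       PropertyTag.DECREASING_ASYMPTOTICALLY_NULL):
                params[name] = 1.0
            else:
                params[name] = float(rng.integers(max(lo, 2), hi + 1))
        else:
            lo, hi = config.range_for(name)
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return params


@dataclass(frozen=True)
class ConcreteInstance:
    """One member of the family realized by a qualitative model."""

    model: NetworkModel
    assignments: dict  # term name -> ParametricFunction
    modulator_assignments: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)
    seed: int | None = None

    def fn(self, term_name: str) -> ParametricFunction:
        return self.assignments[term_name]

    def param(self, term_name: str, param_name: str) -> float:
        return float(self.assignments[term_name].parameters[param_name])

    def with_param(self, term_name: str, **updates) -> "ConcreteInstance":
        """Copy with one term's parameters changed (coupled terms follow)."""
        term = next(t for t in self.model.terms if t.name == term_name)
        new_assign = dict(self.assignments)
        group = [t.name for t in self.model.terms
                 if term.coupling_id is not None
                 and t.coupling_id == term.coupling_id] or [term_name]
        f = self.assignments[term_name]
        params = dict(f.parameters)
        params.update(updates)
        newf = make_function(f.family_id, params, f.claimed_tag)
        for name in group:
            new_assign[name] = newf
        return ConcreteInstance(self.model, new_assign,
                                dict(self.modulator_assignments),
                                dict(self.constants), self.seed)

    def to_json(self) -> str:
        return json.dumps({
            "model": self.model.name,
            "seed": self.seed,
            "constants": self.constants,
            "assignments": {k: v.to_dict() for k, v in self.assignments.items()},
            "modulators": {k: [m.to_dict() for m in v]
                           for k, v in self.modulator_assignments.items()},
        }, indent=2, sort_keys=True)


def sample_instance(model: NetworkModel, config: SamplingConfig | None = None,
                    seed: int | np.random.SeedSequence = 0,
                    verify: bool = True) -> ConcreteInstance:
    """Draw one concrete instance; a pure function of (model, config, seed).

    Coupled terms (shared ``coupling_id``) receive the identical function
    object.  With ``verify=True`` every assignment is re-checked against
    its term's tag and the vanishing-at-zero structure (A5) is spot-checked
    numerically; a failure raises :class:`ConfigurationError` naming the
    term.
    """
    config = config or SamplingConfig()
    report = validate_model(model)
    if not report:
        raise ConfigurationError(
            f"model {model.name!r} fails validation: {report.diagnostics}")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    seed_val = int(ss.entropy) if isinstance(ss.entropy, int) else None

    assignments: dict[str, ParametricFunction] = {}
    mod_assignments: dict[str, tuple] = {}
    coupling_cache: dict[str, ParametricFunction] = {}
    for t in model.terms:
        if t.coupling_id is not None and t.coupling_id in coupling_cache:
            assignments[t.name] = coupling_cache[t.coupling_id]
        else:
            tag = PropertyTag(t.tag)
            family = t.family or TAG_DEFAULT_FAMILY.get(tag)
            if family is None:
                raise ConfigurationError(
                    f"term {t.name!r}: no family admissible for tag {tag}")
            overrides = config.term_params.get(t.name, {})
            params = _draw_params(family, tag, rng, config, overrides)
            f = make_function(family, params, tag)
            assignments[t.name] = f
            if t.coupling_id is not None:
                coupling_cache[t.coupling_id] = f
        mods = []
        for k, (mref, mtag) in enumerate(t.modulators):
            mtag = PropertyTag(mtag)
            fam = TAG_DEFAULT_FAMILY[mtag]
            overrides = config.modulator_params.get(t.name, {})
            params = _draw_params(fam, mtag, rng, config, overrides)
            mods.append(make_function(fam, params, mtag))
        if mods:
            mod_assignments[t.name] = tuple(mods)

    constants = {}
    for name, spec in config.constants.items():
        if isinstance(spec, (tuple, list)):
            lo, hi = float(spec[0]), float(spec[1])
            constants[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            constants[name] = float(spec)

    inst = ConcreteInstance(model=model, assignments=assignments,
                            modulator_assignments=mod_assignments,
                            constants=constants, seed=seed_val)
    if verify:
        for t in model.terms:
            rep = verify_property(assignments[t.name], PropertyTag(t.tag))
            if not rep:
                raise ConfigurationError(
                    f"term {t.name!r}: sampled {assignments[t.name].family_id} "
                    f"violates {t.tag}: {rep.violated}")
        bad = check_a5(model, inst)
        if bad:
            raise ConfigurationError(f"A5 violated for terms {bad}")
    return inst


def check_a5(model: NetworkModel, instance: ConcreteInstance,
             n_grid: int = 10, tol: float = 1e-9) -> list[str]:
    """Numeric spot-check: off-target conversion fluxes vanish when the
    target is 0, probed on a grid of the other variables."""
    from .dynamics import term_flux

    bad = []
    grid = np.geomspace(1e-2, 1e2, n_grid)
    for t in model.terms:
        off_target = (t.kind == "b" and not t.saturating_flux
                      and t.mult is not None and t.mult != t.target
                      and t.mult < model.n_states)
        sat = t.saturating_flux
        if not (off_target or sat):
            continue
        scale = 0.0
        worst = 0.0
        for g in grid:
            x = np.full(model.n_vars, g)
            x[t.target] = 0.0
            val = abs(float(term_flux(t, instance, x)))
            ref = abs(float(term_flux(t, instance, np.full(model.n_vars, g))))
            worst = max(worst, val)
            scale = max(scale, ref)
        if worst > tol * max(scale, 1.0):
            bad.append(t.name)
    return bad


def generate_ensemble(model: NetworkModel, n: int,
                      config: SamplingConfig | None = None,
                      seed: int = 0, verify: bool = True) -> list[ConcreteInstance]:
    """``n`` instances with counter-split sub-seeds; reproducible from
    (model, config, n, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    return [sample_instance(model, config, child, verify=verify)
            for child in ss.spawn(n)]
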