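"""Case-study scaffolding: packaged model + frozen default instance +
claim descriptors runnable over seeded ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..ensemble import ConcreteInstance, SamplingConfig, sample_instance
from ..io import load_packaged_model
from ..model import NetworkModel


@dataclass
class ClaimResult:
    claim_id: str
    holds: bool
    details: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.holds)


@dataclass
class Claim:
    """One proposition-check descriptor.

    ``scope`` is ``"ensemble"`` (checked per sampled instance) or
    ``"default"`` (checked once on the frozen default instance).  The
    procedure receives ``(case, instance, seed)`` and returns a
    :class:`ClaimResult`.
    """

    claim_id: str
    description: str
    procedure: Callable
    scope: str = "ensemble"


@dataclass
class CaseStudy:
    name: str
    model: NetworkModel
    default_instance: ConcreteInstance
    sampling_config: SamplingConfig
    default_inputs: dict = field(default_factory=dict)
    claims: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def sample(self, seed) -> ConcreteInstance:
        return sample_instance(self.model, self.sampling_config, seed)

    def claim(self, claim_id: str) -> Claim:
        for c in self.claims:
            if c.claim_id == claim_id:
                return c
        raise KeyError(claim_id)


_BUILDERS: dict[str, Callable[[], CaseStudy]] = {}


def register_case(name: str):
    def deco(fn):
        _BUILDERS[name] = fn
        return fn
    return deco


def case_names() -> list[str]:
    return sorted(_BUILDERS)


def build_case(name: str) -> CaseStudy:
    if name not in _BUILDERS:
        raise KeyError(f"unknown case {name!r}; known: {case_names()}")
    return _BUILDERS[name]()


def frozen_config(term_params: dict, constants: dict | None = None,
                  modulator_params: dict | None = None) -> SamplingConfig:
    """A sampling config whose every parameter is pinned, so the default
    instance is the same for any seed."""
    return SamplingConfig(term_params=term_params,
                          modulator_params=modulator_params or {},
                          constants=constants or {})


def load(name: str) -> NetworkModel:
    return load_packaged_model(name)


def random_x0(box, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    hi = np.where(np.isfinite(box), box, 1.0) * scale
    return rng.uniform(0.0, 1.0, size=len(hi)) * hi
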