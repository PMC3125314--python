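"""Qualitative property tags for interaction terms.

Each tag names a shape class for a scalar nonnegative function on [0, inf):
sign, monotonicity, behaviour at 0 and at infinity, and (for the sigmoid
classes) unimodality of the derivative.  Tags are the only information a
qualitative network model carries about its nonlinearities; concrete
parametric families realizing each tag live in :mod:`robnet.functions`.
"""

from __future__ import annotations

from enum import Enum


class PropertyTag(str, Enum):
    """Shape classes for interaction-term functions."""

    NONNEGATIVE_CONSTANT = "nonnegative-constant"
    POSITIVE_CONSTANT = "positive-constant"
    SIGMOIDAL = "sigmoidal"
    COMPLEMENTARY_SIGMOIDAL = "complementary-sigmoidal"
    CONSTANT_SIGMOIDAL = "constant-sigmoidal"
    CONSTANT_COMPLEMENTARY_SIGMOIDAL = "constant-complementary-sigmoidal"
    INCREASING_ASYMPTOTICALLY_CONSTANT = "increasing-asymptotically-constant"
    DECREASING_ASYMPTOTICALLY_NULL = "decreasing-asymptotically-null"
    DECREASING_EXACTLY_NULL = "decreasing-exactly-null"
    INCREASING_ASYMPTOTICALLY_UNBOUNDED = "increasing-asymptotically-unbounded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Tags whose functions are non-decreasing (admissible for saturating
#: production terms of kind ``c``; the zero constant is excluded because a
#: ``c`` term must have a positive upper saturation level).
NON_DECREASING_TAGS = frozenset(
    {
        PropertyTag.POSITIVE_CONSTANT,
        PropertyTag.SIGMOIDAL,
        PropertyTag.CONSTANT_SIGMOIDAL,
        PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT,
        PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED,
    }
)

#: Tags whose functions are non-increasing with a positive value at 0
#: (admissible for decreasing saturating production terms of kind ``d``).
NON_INCREASING_TAGS = frozenset(
    {
        PropertyTag.POSITIVE_CONSTANT,
        PropertyTag.COMPLEMENTARY_SIGMOIDAL,
        PropertyTag.CONSTANT_COMPLEMENTARY_SIGMOIDAL,
        PropertyTag.DECREASING_ASYMPTOTICALLY_NULL,
        PropertyTag.DECREASING_EXACTLY_NULL,
    }
)

#: Tags guaranteeing f(0) = 0 (required of coefficient functions that must
#: vanish at the lower saturation level, and of saturating degradation
#: fluxes so the positive orthant stays invariant).
VANISHING_AT_ZERO_TAGS = frozenset(
    {
        PropertyTag.SIGMOIDAL,
        PropertyTag.INCREASING_ASYMPTOTICALLY_CONSTANT,
        PropertyTag.INCREASING_ASYMPTOTICALLY_UNBOUNDED,
    }
)
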