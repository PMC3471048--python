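"""Generic dual-system valuation of a risky choice.

The dual system model (DSM) scores a risky choice ``C`` with outcomes
``x_i`` occurring with probabilities ``p_i`` as a convex combination of an
intuitive (system I) and a deliberative (system II) valuation::

    E(C) = gamma * (1/n) * sum_i x_i**m_I  +  (1 - gamma) * k * sum_i p_i * x_i

System I is sensitive only to which outcomes are possible: every listed
outcome gets equal weight ``1/n`` and probabilities are ignored.  System II
is linear expected utility.  ``gamma`` in [0, 1] is the relative involvement
of system I, ``k > 0`` rescales the system II term, and ``m_I`` in (0, 1] is
the curvature of the system I power value function (concave for gains).

Outcome values are required strictly positive: the power value function at 0
with fractional exponent is a boundary the model never uses, and utilities
are assumed positive throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "Outcome",
    "RiskyChoice",
    "DualWeights",
    "value_system1",
    "value_system2",
    "dsm_value",
    "compare_choices",
    "INDIFFERENCE_TOL",
]

#: Absolute tolerance below which two valuations count as indifferent.
#: All arithmetic here is closed-form double precision, so this is generous.
INDIFFERENCE_TOL = 1e-12

_PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Outcome:
    """One outcome of a risky choice: a positive utility and a probability."""

    value: float
    probability: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(f"outcome value must be > 0, got {self.value}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"outcome probability must be in [0, 1], got {self.probability}"
            )


@dataclass(frozen=True)
class RiskyChoice:
    """An ordered collection of outcomes forming one decision alternative.

    Duplicate outcome values are deliberately *not* coalesced: the system I
    term divides by the number of listed outcomes, so event splitting changes
    the intuitive valuation.  That sensitivity is a feature of the model.
    """

    outcomes: tuple[Outcome, ...]
    label: str = ""

    def __post_init__(self) -> None:
        outcomes = tuple(self.outcomes)
        object.__setattr__(self, "outcomes", outcomes)
        if len(outcomes) < 1:
            raise ValueError("a risky choice needs at least one outcome")
        total = math.fsum(o.probability for o in outcomes)
        if abs(total - 1.0) > _PROB_SUM_TOL:
            raise ValueError(f"outcome probabilities sum to {total!r}, not 1")

    @property
    def n(self) -> int:
        return len(self.outcomes)


@dataclass(frozen=True)
class DualWeights:
    """Model parameters: system I involvement, system II scale, curvature.

    gamma : weight on system I, in [0, 1].
    k     : scaling constant on the system II (expected utility) term, > 0.
    m_i   : exponent of the system I power value function, in (0, 1].
    """

    gamma: float
    k: float = 1.0
    m_i: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (0.0 < self.m_i <= 1.0):
            raise ValueError(f"m_i must be in (0, 1], got {self.m_i}")


def value_system1(choice: RiskyChoice, weights: DualWeights) -> float:
    """Intuitive valuation: equal-weight mean of x_i**m_I.

    Independent of the outcomes' probabilities by construction — system I
    registers only that an outcome is possible.
    """
    m = weights.m_i
    return math.fsum(o.value**m for o in choice.outcomes) / choice.n


def value_system2(choice: RiskyChoice, weights: DualWeights) -> float:
    """Deliberative valuation: k times the expected utility sum(p_i * x_i)."""
    return weights.k * math.fsum(o.probability * o.value for o in choice.outcomes)


def dsm_value(choice: RiskyChoice, weights: DualWeights) -> float:
    """Combined valuation gamma*V_I + (1-gamma)*V_II."""
    g = weights.gamma
    return g * value_system1(choice, weights) + (1.0 - g) * value_system2(
        choice, weights
    )


def compare_choices(
    a: RiskyChoice,
    b: RiskyChoice,
    weights: DualWeights,
    *,
    tol: float = INDIFFERENCE_TOL,
) -> Literal["a", "b", "indifferent"]:
    """Preference by value maximization over the combined valuation."""
    diff = dsm_value(a, weights) - dsm_value(b, weights)
    if abs(diff) <= tol:
        return "indifferent"
    return "a" if diff > 0 else "b"
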