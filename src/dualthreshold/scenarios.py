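"""Worked-example fixtures, random scenario generation, and an independent
indifference-point oracle.

The oracle finds the disease probability at which the valuations of treating
and not treating are equal by bracketing the root of their difference — it
never touches the closed-form threshold expression, so any disagreement
between the two is diagnostic of an implementation defect rather than shared
bias.  The valuation difference is linear in p with strictly positive slope
(1-gamma) * k * (b2 + h2), so the root is unique whenever gamma < 1; it may,
however, lie outside [0, 1], which is why the search runs over an extended
interval.

Bundled fixtures encode two published clinical scenarios:

* anticoagulation for suspected pulmonary embolism (PE) — evidence-based
  net benefit 17.5-22.5 percentage points of absolute mortality reduction
  against net harm 0.37-5 points of life-threatening bleeding;
* allogeneic stem-cell transplant for intermediate-risk acute myeloid
  leukemia (AML) — 12-point leukemia-free-survival benefit against 16-point
  treatment-related mortality, with system I harm perceived doubled
  (pessimistic) or halved (optimistic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Any

import numpy as np
from scipy.optimize import brentq

from .threshold import (
    BenefitHarmProfile,
    OutcomeQuadruple,
    profile_from_outcomes,
    valuation_notreat,
    valuation_treat,
)
from .valuation import DualWeights

__all__ = [
    "ScenarioFixture",
    "bundled_examples",
    "random_scenarios",
    "numeric_indifference",
    "numeric_indifference_profile",
    "DEFAULT_SEED",
    "ORACLE_BRACKET",
]

#: Default seed for reproducible scenario generation; any seed is accepted.
DEFAULT_SEED = 20120903

#: Search interval for the indifference point, in raw threshold space, wide
#: enough to capture roots far outside [0, 1].
ORACLE_BRACKET = (-10.0, 10.0)

_ORACLE_XTOL = 1e-14


@dataclass(frozen=True)
class ScenarioFixture:
    """One named scenario: a profile, weights, optionally the source quad
    and expected threshold values with provenance notes."""

    name: str
    profile: BenefitHarmProfile
    weights: DualWeights
    quad: OutcomeQuadruple | None = None
    expected: dict[str, Any] | None = None


def bundled_examples() -> list[ScenarioFixture]:
    """Load the packaged worked-example fixtures."""
    text = resources.files("dualthreshold").joinpath("data/examples.json").read_text()
    raw = json.loads(text)
    fixtures = []
    for entry in raw["examples"]:
        prof = entry["profile"]
        par = entry["parameters"]
        fixtures.append(
            ScenarioFixture(
                name=entry["name"],
                profile=BenefitHarmProfile(
                    b2=prof["b2"], h2=prof["h2"], b1=prof["b1"], h1=prof["h1"]
                ),
                weights=DualWeights(
                    gamma=par["gamma"], k=par.get("k", 1.0), m_i=par.get("m_I", 1.0)
                ),
                expected=entry.get("expected"),
            )
        )
    return fixtures


def random_scenarios(seed: int, count: int) -> list[ScenarioFixture]:
    """Reproducible random treat/no-treat scenarios for property testing.

    Outcome quadruples are drawn in (0, 1] with x1 > x3 and x4 > x2 (the
    standard clinical ordering), gamma uniform on [0, 0.99], m_I uniform on
    (0, 1], and k from {0.5, 1, 2}.  The profile is derived from the quad
    with the drawn m_I.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    fixtures = []
    for i in range(count):
        lo, hi = np.sort(rng.uniform(1e-3, 1.0, size=2))
        while hi <= lo:  # pragma: no cover - measure-zero resample
            lo, hi = np.sort(rng.uniform(1e-3, 1.0, size=2))
        x3, x1 = float(lo), float(hi)
        lo, hi = np.sort(rng.uniform(1e-3, 1.0, size=2))
        while hi <= lo:  # pragma: no cover
            lo, hi = np.sort(rng.uniform(1e-3, 1.0, size=2))
        x2, x4 = float(lo), float(hi)
        weights = DualWeights(
            gamma=float(rng.uniform(0.0, 0.99)),
            k=float(rng.choice([0.5, 1.0, 2.0])),
            m_i=float(1.0 - rng.uniform(0.0, 0.999)),
        )
        quad = OutcomeQuadruple(x1=x1, x2=x2, x3=x3, x4=x4)
        fixtures.append(
            ScenarioFixture(
                name=f"random_{seed}_{i}",
                profile=profile_from_outcomes(quad, weights),
                weights=weights,
                quad=quad,
            )
        )
    return fixtures


def _bracketed_root(diff, lo: float, hi: float) -> float | None:
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None  # no sign change: root outside the extended interval
    return float(brentq(diff, lo, hi, xtol=_ORACLE_XTOL))


def numeric_indifference(
    quad: OutcomeQuadruple, weights: DualWeights
) -> float | None:
    """Indifference probability by root bracketing over the valuations.

    Solves valuation_treat(p) = valuation_notreat(p) on the extended
    interval; returns None if no root lies there.  Requires gamma < 1 (a
    pure system I decision-maker has no indifference probability).
    """
    if weights.gamma >= 1.0:
        raise ValueError("numeric_indifference requires gamma < 1")

    def diff(p: float) -> float:
        return valuation_treat(p, quad, weights) - valuation_notreat(
            p, quad, weights
        )

    return _bracketed_root(diff, *ORACLE_BRACKET)


def numeric_indifference_profile(
    profile: BenefitHarmProfile, weights: DualWeights
) -> float | None:
    """Oracle variant for directly elicited benefit/harm profiles.

    Uses the same treat-minus-no-treat valuation difference expressed in
    profile terms: the system I branches contribute (gamma/2)(b1 - h1) and
    the system II branches (1-gamma) k (p b2 - (1-p) h2).  Still avoids the
    closed-form threshold entirely.
    """
    if weights.gamma >= 1.0:
        raise ValueError("numeric_indifference_profile requires gamma < 1")
    g, k = weights.gamma, weights.k

    def diff(p: float) -> float:
        return (g / 2.0) * (profile.b1 - profile.h1) + (1.0 - g) * k * (
            p * profile.b2 - (1.0 - p) * profile.h2
        )

    return _bracketed_root(diff, *ORACLE_BRACKET)
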