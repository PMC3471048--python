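"""Treat / no-treat decision thresholds under dual-process valuation.

The clinical dilemma: treat (Rx) or withhold treatment (NoRx) when the
disease is present with probability ``p``.  Four outcome utilities enter:

====  =================  =========================================
cell  action, disease    utility
====  =================  =========================================
x1    Rx,   D+           treated patient who had the disease
x2    Rx,   D-           treated patient who did not have it
x3    NoRx, D+           untreated patient who had the disease
x4    NoRx, D-           untreated patient who did not have it
====  =================  =========================================

System II works with the evidence-based net benefit ``B_II = x1 - x3`` and
net harm ``H_II = x4 - x2``.  System I values each action branch by
anticipated regret (the loss relative to the action that was right in
retrospect), yielding the subjective net benefit ``B_I = x1^m - x3^m`` and
net harm ``H_I = x4^m - x2^m`` — or, in practice, directly elicited "gist"
magnitudes.  Setting the combined valuations of Rx and NoRx equal and
solving for ``p`` gives the dual decision threshold

    p_t = p_EUT - (gamma / (2 (1-gamma) k)) * (B_I - H_I) / (B_II + H_II)

with the classical expected-utility threshold ``p_EUT = H_II/(B_II+H_II)``
as the gamma = 0 limit.  Treat when the disease probability exceeds p_t.

The raw threshold can leave [0, 1]: p_t <= 0 means treat at any probability
(always-treat regime), p_t >= 1 means never treat.  At gamma = 1 the
threshold is undefined (pure system I ignores probability altogether) and
the decision is categorical on the sign of B_I - H_I.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Literal

from .valuation import INDIFFERENCE_TOL, DualWeights

__all__ = [
    "OutcomeQuadruple",
    "RegretTable",
    "BenefitHarmProfile",
    "Regime",
    "ThresholdResult",
    "regret_values",
    "profile_from_outcomes",
    "valuation_treat",
    "valuation_notreat",
    "eut_threshold",
    "dual_threshold",
    "decide",
    "critical_gamma",
]


@dataclass(frozen=True)
class OutcomeQuadruple:
    """Utilities of the four treat/disease cells, all strictly positive.

    In the standard profile treatment helps the diseased (x1 > x3) and harms
    the healthy (x4 > x2); pass ``non_standard=True`` to lift those two
    ordering constraints.
    """

    x1: float
    x2: float
    x3: float
    x4: float
    non_standard: bool = False

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3", "x4"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.non_standard:
            if not (self.x1 > self.x3):
                raise ValueError(
                    "standard profile requires x1 > x3 (treatment benefits "
                    "the diseased); pass non_standard=True to allow this"
                )
            if not (self.x4 > self.x2):
                raise ValueError(
                    "standard profile requires x4 > x2 (treatment harms "
                    "the non-diseased); pass non_standard=True to allow this"
                )


@dataclass(frozen=True)
class RegretTable:
    """System I regret values per cell; right-in-retrospect cells carry 0."""

    rg_rx_dpos: float
    rg_norx_dpos: float
    rg_rx_dneg: float
    rg_norx_dneg: float

    def __post_init__(self) -> None:
        if self.rg_rx_dpos != 0.0 or self.rg_norx_dneg != 0.0:
            raise ValueError(
                "treating the diseased and not treating the healthy were "
                "right in retrospect: their regret must be 0"
            )


@dataclass(frozen=True)
class BenefitHarmProfile:
    """Net benefit and harm as seen by each system.

    b2, h2 : evidence-based (system II) net benefit and harm, e.g. absolute
             risk differences as fractions; both must be positive.
    b1, h1 : the system I counterparts — regret-derived or directly elicited
             gist magnitudes; non-negative unless ``non_standard``.
    """

    b2: float
    h2: float
    b1: float
    h1: float
    non_standard: bool = False

    def __post_init__(self) -> None:
        if not (self.b2 > 0):
            raise ValueError(f"b2 must be > 0, got {self.b2}")
        if not (self.h2 > 0):
            raise ValueError(f"h2 must be > 0, got {self.h2}")
        for name in ("b1", "h1"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if not self.non_standard and v < 0:
                raise ValueError(
                    f"{name} must be >= 0 in standard mode, got {v}; "
                    "pass non_standard=True to allow this"
                )


class Regime(str, enum.Enum):
    """Decision regime implied by the raw dual threshold."""

    INTERIOR = "interior"
    ALWAYS_TREAT = "always_treat"
    NEVER_TREAT = "never_treat"
    SYSTEM1_ONLY = "system1_only"


@dataclass(frozen=True)
class ThresholdResult:
    """EUT threshold, raw and clamped dual thresholds, and the regime.

    ``p_dual_raw`` may fall outside [0, 1]; ``p_dual`` is its clamp onto
    [0, 1].  Both are ``None`` in the system1_only regime (gamma = 1), where
    no probability threshold exists.
    """

    p_eut: float
    p_dual_raw: float | None
    p_dual: float | None
    regime: Regime


def regret_values(quad: OutcomeQuadruple, weights: DualWeights) -> RegretTable:
    """Anticipated regret per cell on the system I (power-valued) scale.

    Only the two retrospectively wrong actions regret anything: failing to
    treat the diseased (x3^m - x1^m, a loss when x1 > x3) and treating the
    healthy (x2^m - x4^m, a loss when x4 > x2).
    """
    m = weights.m_i
    return RegretTable(
        rg_rx_dpos=0.0,
        rg_norx_dpos=quad.x3**m - quad.x1**m,
        rg_rx_dneg=quad.x2**m - quad.x4**m,
        rg_norx_dneg=0.0,
    )


def profile_from_outcomes(
    quad: OutcomeQuadruple, weights: DualWeights
) -> BenefitHarmProfile:
    """Derive the benefit/harm profile from the four cell utilities."""
    m = weights.m_i
    return BenefitHarmProfile(
        b2=quad.x1 - quad.x3,
        h2=quad.x4 - quad.x2,
        b1=quad.x1**m - quad.x3**m,
        h1=quad.x4**m - quad.x2**m,
        non_standard=quad.non_standard,
    )


def valuation_treat(
    p: float, quad: OutcomeQuadruple, weights: DualWeights
) -> float:
    """Combined valuation of treating at disease probability p.

    System I contributes the equal-weight mean of the two treat-branch regret
    values (only the Rx,D- cell is non-zero); system II the expected utility
    of the treat branch.
    """
    g, k, m = weights.gamma, weights.k, weights.m_i
    return (g / 2.0) * (quad.x2**m - quad.x4**m) + (1.0 - g) * k * (
        p * quad.x1 + (1.0 - p) * quad.x2
    )


def valuation_notreat(
    p: float, quad: OutcomeQuadruple, weights: DualWeights
) -> float:
    """Combined valuation of withholding treatment at disease probability p."""
    g, k, m = weights.gamma, weights.k, weights.m_i
    return (g / 2.0) * (quad.x3**m - quad.x1**m) + (1.0 - g) * k * (
        p * quad.x3 + (1.0 - p) * quad.x4
    )


def eut_threshold(profile: BenefitHarmProfile) -> float:
    """Classical expected-utility threshold h2 / (b2 + h2) = 1/(1 + b2/h2)."""
    return profile.h2 / (profile.b2 + profile.h2)


def dual_threshold(
    profile: BenefitHarmProfile, weights: DualWeights
) -> ThresholdResult:
    """Dual-process decision threshold and its regime.

    Computed as p_EUT minus the system I correction
    (gamma / (2 (1-gamma) k)) * (b1 - h1) / (b2 + h2), so the gamma = 0 and
    b1 = h1 reductions to p_EUT are exact.  At gamma = 1 the correction
    diverges: the result carries regime ``SYSTEM1_ONLY`` and no thresholds;
    :func:`decide` then falls back to the sign of b1 - h1.
    """
    p_eut = eut_threshold(profile)
    g, k = weights.gamma, weights.k
    if g == 1.0:
        return ThresholdResult(
            p_eut=p_eut, p_dual_raw=None, p_dual=None, regime=Regime.SYSTEM1_ONLY
        )
    correction = (g / (2.0 * (1.0 - g) * k)) * (profile.b1 - profile.h1) / (
        profile.b2 + profile.h2
    )
    raw = p_eut - correction
    if raw <= 0.0:
        regime = Regime.ALWAYS_TREAT
    elif raw >= 1.0:
        regime = Regime.NEVER_TREAT
    else:
        regime = Regime.INTERIOR
    return ThresholdResult(
        p_eut=p_eut,
        p_dual_raw=raw,
        p_dual=min(1.0, max(0.0, raw)),
        regime=regime,
    )


def decide(
    p: float,
    result: ThresholdResult,
    profile: BenefitHarmProfile,
    *,
    tol: float = INDIFFERENCE_TOL,
) -> Literal["treat", "no_treat", "indifferent"]:
    """Treat when the disease probability exceeds the threshold.

    Ties within ``tol`` are reported as indifferent.  In the system1_only
    regime probability plays no role and the decision is the sign of b1 - h1.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if result.regime is Regime.SYSTEM1_ONLY:
        diff = profile.b1 - profile.h1
        if abs(diff) <= tol:
            return "indifferent"
        return "treat" if diff > 0 else "no_treat"
    assert result.p_dual_raw is not None
    diff = p - result.p_dual_raw
    if abs(diff) <= tol:
        return "indifferent"
    return "treat" if diff > 0 else "no_treat"


def critical_gamma(
    profile: BenefitHarmProfile,
    k: float = 1.0,
    boundary: Literal["always_treat", "never_treat"] = "never_treat",
) -> float | None:
    """System I involvement at which the raw threshold hits 0 or 1.

    Solving p_raw(gamma) = 1 gives gamma* = b2 / (b2 + (h1 - b1)/(2k)),
    reachable only when h1 > b1 (the threshold rises with gamma); solving
    p_raw(gamma) = 0 gives gamma* = h2 / (h2 + (b1 - h1)/(2k)), reachable
    only when b1 > h1.  Returns None when the requested boundary cannot be
    reached for any gamma in (0, 1) — in particular whenever b1 = h1, where
    the threshold is flat at p_EUT.
    """
    if not (k > 0):
        raise ValueError(f"k must be > 0, got {k}")
    delta = profile.b1 - profile.h1  # system I net inclination to treat
    if boundary == "never_treat":
        if delta >= 0:
            return None
        return profile.b2 / (profile.b2 + (-delta) / (2.0 * k))
    if boundary == "always_treat":
        if delta <= 0:
            return None
        return profile.h2 / (profile.h2 + delta / (2.0 * k))
    raise ValueError(f"unknown boundary {boundary!r}")
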