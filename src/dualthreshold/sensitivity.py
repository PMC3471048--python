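"""One-way sensitivity analysis for the dual decision threshold.

Three sweep styles:

* :func:`gamma_sweep` — threshold as a function of system I involvement, at
  fixed benefit/harm magnitudes; the curve is flat at the expected-utility
  threshold when system I is neutral (b1 = h1), rises with gamma when the
  intuitive system weighs harms above benefits, and falls otherwise.
* :func:`ratio_sweep` — threshold as a function of the evidence-based
  benefit/harm ratio b2/h2, with the expected-utility curve 1/(1 + ratio)
  bracketed by a benefit-dominant (b1 > h1) and a harm-dominant (b1 < h1)
  system I curve.
* :func:`behavior_grid` — threshold over a grid of subjective risk
  perceptions (h1/h2 by b1/h1) at fixed gamma and b2/h2, with cells whose
  raw threshold leaves [0, 1] labelled always-/never-treat.

Plus :func:`gist_round`, the prominent-number heuristic: intuitive magnitude
judgments snap to the series {1, 2, 5} x 10^n.

Every sweep row is an isolated :func:`~dualthreshold.threshold.dual_threshold`
call; results carry no accumulated state and serialize to CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import pandas as pd

from .threshold import BenefitHarmProfile, dual_threshold, eut_threshold
from .valuation import DualWeights

__all__ = [
    "SweepSpec",
    "SweepResult",
    "gamma_sweep",
    "ratio_sweep",
    "behavior_grid",
    "gist_round",
    "figure_gamma_presets",
    "GAMMA_GRID_MAX",
]

#: Default upper end of gamma grids; the closed form divides by (1 - gamma),
#: so sweeps stop just short of 1 and gamma = 1 is handled as a categorical
#: regime, never evaluated.
GAMMA_GRID_MAX = 1.0 - 1e-6


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(min(g / 100.0, GAMMA_GRID_MAX) for g in range(100))


@dataclass(frozen=True)
class SweepSpec:
    """What to sweep: a base profile, a grid, and a system I shift.

    ``system1_shift`` sets the subjective net inclination b1 - h1 for the
    swept curve: h1 is kept at the profile's value and b1 is set to
    h1 + shift.  ``None`` leaves the profile's own b1 and h1 untouched.
    Only the difference b1 - h1 enters the threshold, so this decomposition
    is a convention, not a modelling choice.
    """

    profile: BenefitHarmProfile
    k: float = 1.0
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    ratio_grid: tuple[float, ...] | None = None
    system1_shift: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_grid", tuple(self.gamma_grid))
        if self.ratio_grid is not None:
            object.__setattr__(self, "ratio_grid", tuple(self.ratio_grid))
        for name, grid in (("gamma_grid", self.gamma_grid),
                           ("ratio_grid", self.ratio_grid)):
            if grid is None:
                continue
            if len(grid) == 0:
                raise ValueError(f"{name} must be nonempty")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if any(not (0.0 <= g < 1.0) for g in self.gamma_grid):
            raise ValueError("gamma_grid values must lie in [0, 1)")
        if self.ratio_grid is not None and any(r <= 0 for r in self.ratio_grid):
            raise ValueError("ratio_grid values must be positive")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")

    def effective_profile(self) -> BenefitHarmProfile:
        """Base profile with the system I shift applied (if any)."""
        if self.system1_shift is None:
            return self.profile
        h1 = self.profile.h1
        b1 = h1 + self.system1_shift
        return replace(self.profile, b1=b1, h1=h1, non_standard=b1 < 0)


@dataclass(frozen=True)
class SweepResult:
    """Sweep rows as a DataFrame plus the spec that produced them."""

    frame: pd.DataFrame
    meta: dict[str, Any]

    def to_csv(self, path_or_buf=None, **kwargs):
        """Write the rows as CSV (one header row, one row per grid point)."""
        kwargs.setdefault("index", False)
        return self.frame.to_csv(path_or_buf, **kwargs)

    def plot(self, callback: Callable[[pd.DataFrame], Any] | None = None, ax=None):
        """Render the sweep, or hand the rows to a caller-supplied callback."""
        if callback is not None:
            return callback(self.frame)
        import matplotlib.pyplot as plt  # deferred: plotting is optional

        if ax is None:
            _, ax = plt.subplots()
        grid_var = self.frame["grid_var"].iloc[0]
        x = self.frame["value"]
        ax.plot(x, self.frame["p_eut"], "k:", label="EUT threshold")
        for col in ("p_dual", "p_dual_benefit", "p_dual_harm"):
            if col in self.frame:
                ax.plot(x, self.frame[col], label=col)
        ax.set_xlabel(grid_var)
        ax.set_ylabel("threshold probability")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def _threshold_row(profile: BenefitHarmProfile, weights: DualWeights) -> dict:
    res = dual_threshold(profile, weights)
    return {
        "p_eut": res.p_eut,
        "p_dual_raw": res.p_dual_raw,
        "p_dual": res.p_dual,
        "regime": res.regime.value,
    }


def gamma_sweep(spec: SweepSpec) -> SweepResult:
    """Dual threshold at each gamma grid point (Eq. of the closed form).

    The curve is monotone in gamma: rising when h1 > b1, falling when
    b1 > h1, flat at the expected-utility threshold when they are equal.
    """
    profile = spec.effective_profile()
    rows = []
    for g in spec.gamma_grid:
        weights = DualWeights(gamma=g, k=spec.k)
        rows.append({"grid_var": "gamma", "value": g,
                     **_threshold_row(profile, weights)})
    meta = {"sweep": "gamma", "profile": profile, "k": spec.k,
            "system1_shift": spec.system1_shift}
    return SweepResult(frame=pd.DataFrame(rows), meta=meta)


def ratio_sweep(spec: SweepSpec, gamma: float = 0.5) -> SweepResult:
    """Thresholds as a function of the benefit/harm ratio b2/h2.

    h2 is held at the profile's value and b2 = ratio * h2 at each grid
    point.  Three curves per point: the expected-utility threshold
    1/(1 + ratio), a benefit-dominant system I curve (b1 - h1 = +|shift|,
    below EUT) and a harm-dominant one (b1 - h1 = -|shift|, above EUT).
    ``gamma`` is the fixed system I involvement for both dual curves.
    """
    if spec.ratio_grid is None:
        raise ValueError("ratio_sweep requires a ratio_grid")
    if not (0.0 <= gamma < 1.0):
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    shift = abs(spec.system1_shift if spec.system1_shift is not None else 0.05)
    h2 = spec.profile.h2
    h1 = spec.profile.h1
    weights = DualWeights(gamma=gamma, k=spec.k)
    rows = []
    for r in spec.ratio_grid:
        benefit = BenefitHarmProfile(b2=r * h2, h2=h2, b1=h1 + shift, h1=h1)
        harm = BenefitHarmProfile(b2=r * h2, h2=h2, b1=max(h1 - shift, 0.0),
                                  h1=h1, non_standard=h1 - shift < 0)
        res_b = dual_threshold(benefit, weights)
        res_h = dual_threshold(harm, weights)
        rows.append({
            "grid_var": "ratio",
            "value": r,
            "p_eut": res_b.p_eut,
            "p_dual_raw_benefit": res_b.p_dual_raw,
            "p_dual_benefit": res_b.p_dual,
            "regime_benefit": res_b.regime.value,
            "p_dual_raw_harm": res_h.p_dual_raw,
            "p_dual_harm": res_h.p_dual,
            "regime_harm": res_h.regime.value,
        })
    meta = {"sweep": "ratio", "gamma": gamma, "k": spec.k, "h2": h2,
            "h1": h1, "system1_shift": shift}
    return SweepResult(frame=pd.DataFrame(rows), meta=meta)


def behavior_grid(
    gamma: float,
    ratio: float,
    h1_over_h2_grid: Sequence[float],
    b1_over_h1_grid: Sequence[float],
    k: float = 1.0,
    h2: float = 0.05,
) -> SweepResult:
    """Threshold over a grid of subjective risk perceptions.

    Rows scan h1/h2 (how much larger the felt harm is than the evidence-based
    harm), columns b1/h1 (felt benefit relative to felt harm), at fixed gamma
    and evidence ratio b2/h2.  Because every grid quantity is a ratio to h2,
    the absolute h2 scale cancels out of the threshold; ``h2`` only sets the
    nominal profile magnitudes.  Cells whose raw threshold leaves [0, 1] are
    labelled with their always-/never-treat regime.
    """
    if not (0.0 <= gamma < 1.0):
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if any(v <= 0 for v in h1_over_h2_grid) or any(v <= 0 for v in b1_over_h1_grid):
        raise ValueError("grid values must be positive")
    weights = DualWeights(gamma=gamma, k=k)
    b2 = ratio * h2
    rows = []
    for hr in h1_over_h2_grid:
        h1 = hr * h2
        for br in b1_over_h1_grid:
            b1 = br * h1
            profile = BenefitHarmProfile(b2=b2, h2=h2, b1=b1, h1=h1)
            rows.append({"h1_over_h2": hr, "b1_over_h1": br,
                         **_threshold_row(profile, weights)})
    meta = {"sweep": "behavior_grid", "gamma": gamma, "ratio": ratio,
            "k": k, "h2": h2}
    return SweepResult(frame=pd.DataFrame(rows), meta=meta)


_PROMINENT_MANTISSAS = (1.0, 2.0, 5.0, 10.0)


def gist_round(x: float) -> float:
    """Round to the nearest prominent number {1, 2, 5} x 10^n in log space.

    Models the qualitative magnitude judgments of intuitive reasoning, which
    work with a "1/10 aspiration level" rather than exact values.  Ties in
    log distance resolve to the larger prominent number.
    """
    if not (x > 0):
        raise ValueError(f"gist_round requires x > 0, got {x}")
    exponent = math.floor(math.log10(x))
    best = None
    best_dist = math.inf
    for e in (exponent - 1, exponent, exponent + 1):
        for m in _PROMINENT_MANTISSAS:
            candidate = m * 10.0**e
            dist = abs(math.log10(x) - math.log10(candidate))
            # ties go to the larger prominent number
            if dist < best_dist - 1e-15 or (
                abs(dist - best_dist) <= 1e-15 and candidate > best
            ):
                best, best_dist = candidate, dist
    return best


def figure_gamma_presets(h2: float = 0.05, shift: float = 0.05) -> dict[str, SweepSpec]:
    """Four bundled gamma-sweep presets spanning the evidence regimes.

    Panels: very high benefit/harm ratio (60.8, the best-case pulmonary
    embolism evidence), moderately high (3.5, the worst case), equal, and
    unfavourable (<1).  Each preset pairs with shifts of +/- ``shift`` on
    b1 - h1; the magnitudes for the non-PE panels are illustrative, only the
    b2/h2 ratio is meaningful.
    """
    ratios = {"very_high": 60.8, "moderate": 3.5, "equal": 1.0, "unfavourable": 0.5}
    presets = {}
    for name, r in ratios.items():
        base = BenefitHarmProfile(b2=r * h2, h2=h2, b1=2 * shift, h1=2 * shift)
        for sign, tag in ((+1.0, "benefit_dominant"), (-1.0, "harm_dominant")):
            presets[f"{name}_{tag}"] = SweepSpec(
                profile=base, system1_shift=sign * shift
            )
    return presets
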