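# Methods

## Model

The package implements an additive dual-system valuation of risky choice
and its specialization to the treat/no-treat dilemma.

**Generic valuation** (`valuation.py`). A choice with outcomes `x_i > 0`
and probabilities `p_i` is valued as
`γ · (1/n) Σ x_i^m_I + (1−γ) · k · Σ p_i x_i`. The assumptions that matter:

* System I is sensitive only to the *presence* of outcomes. Every listed
  outcome gets weight `1/n`, so splitting one event into two listed
  outcomes changes the intuitive valuation. Duplicates are therefore never
  coalesced; event-splitting sensitivity is part of the model.
* Outcome values must be strictly positive. The power value function
  `x^m_I` with fractional exponent has a boundary at 0 that the model never
  uses, so 0 is rejected rather than silently accepted.
* System II is linear expected utility — probabilities enter without
  distortion.

**Treatment specialization** (`threshold.py`). Four cell utilities
(`x1` = treated diseased, `x2` = treated healthy, `x3` = untreated
diseased, `x4` = untreated healthy; standard ordering `x1 > x3`,
`x4 > x2`). System I values each action branch by anticipated regret: the
two retrospectively correct cells carry zero regret, failing to treat the
diseased carries `x3^m − x1^m`, treating the healthy `x2^m − x4^m`. With
net benefit/harm pairs `B_II = x1 − x3`, `H_II = x4 − x2` (evidence-based)
and `B_I = x1^m − x3^m`, `H_I = x4^m − x2^m` (felt), equating the two
action valuations gives the dual threshold. We evaluate it in the
factorized form

```
p_raw = H_II/(B_II+H_II) − γ/(2(1−γ)k) · (B_I−H_I)/(B_II+H_II)
```

rather than as a single ratio of sums. The two are algebraically
identical; the factorized form makes two structural identities *exact* in
floating point: γ = 0 reduces to the expected-utility threshold, and
`B_I = H_I` gives the expected-utility threshold at every γ < 1.

Profiles can be built two ways — derived from an outcome quadruple, or
given directly as four benefit/harm magnitudes (the usual situation: felt
benefit and harm are elicited as gist quantities, not computed from
utilities). The two construction paths are explicit and never mixed
silently. Only the difference `B_I − H_I` enters the threshold, so any
decomposition of a stated difference into `b1` and `h1` is a convention;
the bundled fixtures document theirs.

## Parameters

| parameter | meaning | range | default |
|---|---|---|---|
| γ | relative involvement of system I | [0, 1] | none (scenario input) |
| k | scale of the system II term | > 0 | 1 (the conventional choice) |
| m_I | curvature of the system I power value function | (0, 1] | 1 |

All benefits, harms and utilities are dimensionless fractions (e.g.
absolute risk differences). Computation is entirely in fractions; percent
appears only at the I/O boundary, formatted to one decimal in
human-readable output and kept at full precision in JSON/CSV.

## Degenerate cases and numerical choices

* **γ = 1.** The closed form divides by (1−γ). Rather than evaluating
  near-singular expressions, γ = 1 is a dedicated `system1_only` regime
  with no probability threshold; the decision is the sign of `B_I − H_I`.
  Sweeps stop their γ grids below 1 (default grid tops out at 0.99, the
  hard cap is 1 − 1e−6).
* **Raw thresholds outside [0, 1]** are reported both raw and clamped, with
  regime labels `always_treat` (raw ≤ 0) and `never_treat` (raw ≥ 1). The
  raw value is what critical-γ analysis needs; the clamped value carries
  the decision semantics.
* **Critical γ** values solve `p_raw = 1` (never-treat,
  `γ* = B_II/(B_II + (H_I−B_I)/2k)`, reachable only when `H_I > B_I`) and
  `p_raw = 0` (always-treat, `γ* = H_II/(H_II + (B_I−H_I)/2k)`, reachable
  only when `B_I > H_I`); unreachable boundaries return `None`.
* **Ties.** A disease probability exactly at the threshold (within 1e−12
  absolute) is reported `indifferent`, not `treat`: only strictly exceeding
  the threshold favors treatment. The same 1e−12 governs choice
  comparison; all arithmetic is closed-form double precision, so this is
  conservative.
* **Gist rounding** uses the prominent-number series {1, 2, 5}×10ⁿ with
  nearest-neighbor in log₁₀ distance and ties to the larger number. The
  series is standard; the metric and tie-break are our choices (the log
  metric is the natural one for a ratio scale). Constraining user inputs
  to prominent numbers is deliberately *not* done — `gist_round` is offered
  as an explicit preprocessing step, off by default.

## Verification strategy

An independent oracle (`scenarios.numeric_indifference`) finds the
indifference probability by bracketing the root of
`valuation_treat(p) − valuation_notreat(p)` (scipy `brentq`,
xtol 1e−14, interval p ∈ [−10, 10] to capture out-of-[0, 1] roots). It
never touches the closed-form threshold, so oracle/closed-form agreement
(tested on 1000 seeded random scenarios, tolerance 1e−12 in the unit suite)
is diagnostic of implementation defects. The difference is linear in p with
slope `(1−γ)k(B_II+H_II) > 0`, so the root is unique for γ < 1; roots
outside the extended interval are reported as absent and must coincide
with |raw| > 10.

Random scenarios draw quadruples in (0, 1] with the standard ordering,
γ uniform on [0, 0.99], m_I uniform on (0, 1], k from {0.5, 1, 2} — wide
enough that all three threshold regimes occur in 1000 draws. The default
seed 20120903 is recorded in `scenarios.DEFAULT_SEED`; any seed works.

## What the fixtures and generator do and do not show

The bundled fixtures are desk-scale published clinical scenarios
(pulmonary-embolism anticoagulation; AML transplant consolidation) with
their printed thresholds as expected values. One source inconsistency is
handled explicitly: the pulmonary-embolism best case prints the
benefit/harm ratio as 60.8 alongside the pair 22.5%/0.037%, whose quotient
is ≈608; the printed downstream threshold (1.6%) uses 60.8, so the package
follows the ratio and the fixture uses `h2 = 0.0037` (i.e. 0.37%), which
realizes 60.8 exactly. The best/worst pairing for the worst-case dual
threshold takes `B_II = 0.175` with `H_II = 0.05`, which reproduces the
printed 0.966 and the saturating γ of 0.78.

The random-scenario generator samples utilities and parameters, not
clinicians: passing property tests shows the algebra and its invariants
(reduction to expected utility, side and monotonicity of the system I
correction, k-invariance of the side) hold over the full parameter space,
not that the model describes real physician behavior. Empirical
validation — estimating γ from observed decisions — is out of scope, as is
any extension to diagnostic testing.

## Sweeps

`gamma_sweep` and `ratio_sweep` evaluate the closed form row by row; every
row is reproducible by an isolated `dual_threshold` call (no accumulated
state), and results serialize to stable CSV. `behavior_grid` scans felt
risk perception (`H_I/H_II` by `B_I/H_I`) at fixed γ and evidence ratio;
all grid quantities are ratios to `H_II`, so the absolute harm scale
cancels out of the threshold (asserted in tests) and the nominal
`h2 = 0.05` is cosmetic. The bundled γ-sweep presets span evidence ratios
{60.8, 3.5, 1, 0.5} with felt-balance shifts of ±0.05; only the 60.8 and
3.5 panels correspond to published magnitudes (the pulmonary-embolism best
and worst cases), the others are illustrative regimes.
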