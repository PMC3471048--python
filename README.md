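# dualthreshold

Dual-process (system I / system II) model of the treat/no-treat decision.

Clinicians rarely act like pure expected-utility maximizers: intuition,
anticipated regret and recent experience shift the disease probability at
which they are willing to treat. `dualthreshold` implements a descriptive
valuation model that combines an intuitive, probability-insensitive
system I with deliberative expected utility (system II) and derives the
resulting decision threshold in closed form. It is aimed at medical
decision-making researchers and health-economics modellers who want to
explore how intuitive benefit/harm perceptions move thresholds away from
the classical normative value — and thereby explain over- and
undertreatment patterns.

## The model

A risky choice *C* with outcomes *x_i* (utilities > 0) occurring with
probabilities *p_i* is valued as

```
V(C) = γ · (1/n) Σᵢ xᵢ^m_I  +  (1−γ) · k · Σᵢ pᵢ xᵢ
```

where γ ∈ [0, 1] is the relative involvement of the intuitive system,
m_I ∈ (0, 1] the curvature of its power value function, and k > 0 a scale
on the expected-utility term. System I weighs every possible outcome
equally — it registers *that* an outcome can happen, not how likely it is.

Specialized to treating (Rx) versus not treating (NoRx) a disease present
with probability *p*, system I values each branch by anticipated regret,
and the indifference probability (the **dual decision threshold**) is

```
p_t = p_EUT − γ / (2(1−γ)k) · (B_I − H_I) / (B_II + H_II)
p_EUT = H_II / (B_II + H_II)
```

with evidence-based net benefit `B_II = x1 − x3` and net harm
`H_II = x4 − x2`, and their felt (system I) counterparts `B_I`, `H_I`.
Treat when the disease probability exceeds `p_t`. When the felt benefit
and harm balance (`B_I = H_I`) the threshold is exactly the classical
expected-utility threshold for every γ; felt benefit dominance pulls the
threshold below it, felt harm dominance pushes it above, and the raw
threshold can leave [0, 1] entirely — the always-treat and never-treat
regimes. At γ = 1 no probability threshold exists and the decision is
categorical on the sign of `B_I − H_I`.

## Worked example

Anticoagulation for suspected pulmonary embolism, worst-case evidence
(absolute mortality reduction 17.5 points against 5 points of
life-threatening bleeding), for a physician whose intuition — primed, say,
by a recent bleeding death — weighs harms 0.10 above benefits and whose
reasoning is strongly intuitive (γ = 0.77):

```
$ dual-threshold compute --b2 0.175 --h2 0.05 --b1 0.175 --h1 0.275 --gamma 0.77
EUT threshold:       22.2%
dual threshold (raw): 0.9662
dual threshold:      96.6%
regime:              interior
```

The normative threshold says treat above a 22.2% probability of embolism;
the dual-process threshold of 96.6% reproduces the near-certainty experts
actually demand before anticoagulating. At γ ≥ 0.78 the raw threshold
exceeds 1 and the physician would never treat:

```
$ dual-threshold compute --b2 0.175 --h2 0.05 --b1 0.175 --h1 0.275 --gamma 0.78
...
regime:              never_treat
```

The same machinery is available as a library:

```python
from dualthreshold import BenefitHarmProfile, DualWeights, dual_threshold

profile = BenefitHarmProfile(b2=0.175, h2=0.05, b1=0.175, h1=0.275)
result = dual_threshold(profile, DualWeights(gamma=0.77))
print(result.p_dual_raw)   # 0.966183574879227
```

Other subcommands: `dual-threshold sweep` (γ or benefit/harm-ratio sweeps
as CSV), `evaluate` (decision at a given disease probability), `examples`
(bundled pulmonary-embolism and leukemia-transplant fixtures) and `check`
(closed form versus an independent root-bracketing oracle on random
scenarios).

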