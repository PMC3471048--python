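{
  "format": "dual-threshold scenario collection",
  "examples": [
    {
      "name": "pe_best_case",
      "description": "Anticoagulation for suspected pulmonary embolism, best-case evidence: absolute mortality reduction 22.5 points vs 0.37 points life-threatening bleeding (b2/h2 = 60.8). System I primed by a recent bleed: felt harm exceeds felt benefit by 0.10; only the difference b1 - h1 enters the threshold, the split is a convention.",
      "profile": {"b2": 0.225, "h2": 0.0037, "b1": 0.175, "h1": 0.275},
      "parameters": {"gamma": 0.77, "k": 1.0, "m_I": 1.0},
      "expected": {
        "p_eut": 0.016178399650196764,
        "provenance": {
          "p_eut": "published worked example: EUT threshold 1/(1+60.8) printed as 1.6%; fixture value is 0.0037/(0.225+0.0037), whose ratio realizes the printed 60.8"
        }
      }
    },
    {
      "name": "pe_worst_case",
      "description": "Anticoagulation for suspected pulmonary embolism, worst-case evidence: benefit 17.5 points vs harm 5 points (b2/h2 = 3.5); system I felt harm exceeds felt benefit by 0.10 at gamma = 0.77.",
      "profile": {"b2": 0.175, "h2": 0.05, "b1": 0.175, "h1": 0.275},
      "parameters": {"gamma": 0.77, "k": 1.0, "m_I": 1.0},
      "expected": {
        "p_eut": 0.2222222222222222,
        "p_dual_raw": 0.966183574879227,
        "gamma_at_never_treat_grid_001": 0.78,
        "provenance": {
          "p_eut": "published worked example: 1/(1+3.5), printed as 22.2%",
          "p_dual_raw": "published worked example: dual threshold printed as 0.966 = 96.6% for k=1",
          "gamma_at_never_treat_grid_001": "published worked example: threshold >= 1 for gamma >= 0.78"
        }
      }
    },
    {
      "name": "aml_harm_doubled",
      "description": "Allogeneic stem-cell transplant for intermediate-risk AML: leukemia-free-survival benefit 12 points vs treatment-related mortality 16 points. Pessimistic system I (recent transplant death) doubles the felt harm to 0.32.",
      "profile": {"b2": 0.12, "h2": 0.16, "b1": 0.12, "h1": 0.32},
      "parameters": {"gamma": 0.5, "k": 1.0, "m_I": 1.0},
      "expected": {
        "p_eut": 0.5714285714285714,
        "critical_gamma_never_treat": 0.5454545454545454,
        "provenance": {
          "p_eut": "published worked example: 1/(1+0.12/0.16) = 0.571, printed as 57.1%",
          "critical_gamma_never_treat": "published worked example: threshold > 100% for gamma exceeding 55%"
        }
      }
    },
    {
      "name": "aml_harm_halved",
      "description": "Same AML transplant evidence with optimistic system I: felt harm halved to 0.08 (patient judged fitter than trial populations).",
      "profile": {"b2": 0.12, "h2": 0.16, "b1": 0.12, "h1": 0.08},
      "parameters": {"gamma": 0.5, "k": 1.0, "m_I": 1.0},
      "expected": {
        "p_eut": 0.5714285714285714,
        "critical_gamma_always_treat": 0.8888888888888888,
        "provenance": {
          "p_eut": "published worked example: 1/(1+0.12/0.16) = 0.571, printed as 57.1%",
          "critical_gamma_always_treat": "published worked example: threshold drops to zero for all gamma > 89%"
        }
      }
    }
  ]
}
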