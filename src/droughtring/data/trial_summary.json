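{
  "description": "Published trial-level summary statistics for the three Norway spruce provenance trials (Dorna Candrenilor, Turda, Zarnesti), 81 provenances planted 1972, cored fall 2020.",
  "total_cores_retained": 2709,
  "trials": {
    "Dorna Candrenilor": {
      "cores_retained": 947,
      "rbar": 0.908,
      "mean_rw_mm": 2.73,
      "resistance_2000": 0.88,
      "resilience_2000": 0.90
    },
    "Turda": {
      "cores_retained": 856,
      "rbar": 0.876,
      "mean_rw_mm": 2.81,
      "resistance_2000": 0.89,
      "resilience_2000": 0.89,
      "relative_resilience_2000": 0.0
    },
    "Zarnesti": {
      "cores_retained": 906,
      "rbar": 0.876,
      "mean_rw_mm": 2.55,
      "resistance_2000": 0.72,
      "resilience_2000": 0.80,
      "recovery_2000": 1.15,
      "recovery_2000_sd": 0.12,
      "relative_resilience_2000": 0.07
    }
  }
}
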