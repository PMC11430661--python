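{
  "version": "1.0",
  "description": "Reference four-parameter logistic percentile parameters for FLI-P score against age in months; reporting recommended from 3 months.",
  "min_age": 3,
  "entries": [
    {"tau": 0.05, "a1": -25.3196, "a2": 58.1656, "a3": 0.0641, "a4": 13.6060},
    {"tau": 0.10, "a1": -13.2335, "a2": 59.2565, "a3": 0.0728, "a4": 16.8049},
    {"tau": 0.16, "a1": -4.2314, "a2": 60.1019, "a3": 0.0938, "a4": 18.9745},
    {"tau": 0.50, "a1": 4.9005, "a2": 63.1047, "a3": 0.1204, "a4": 18.5796},
    {"tau": 0.84, "a1": 12.2876, "a2": 64.0000, "a3": 0.1691, "a4": 16.5906},
    {"tau": 0.90, "a1": 15.1011, "a2": 64.0000, "a3": 0.1978, "a4": 15.5172},
    {"tau": 0.95, "a1": 15.7385, "a2": 64.0000, "a3": 0.2277, "a4": 13.5759}
  ]
}
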