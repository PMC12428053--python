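{
  "description": "Four-category prediction counts per algorithm and compartment, transcribed from the published 123-examination DCI cohort comparison this package models. Category order keys: no_abnormality, underestimated_progressive_infarct, reversible_perfusion_deficit, progressive_infarct.",
  "n": 123,
  "counts": {
    "threshold": {
      "hypoperfused": {"no_abnormality": 33, "underestimated_progressive_infarct": 9, "reversible_perfusion_deficit": 49, "progressive_infarct": 32},
      "core": {"no_abnormality": 54, "underestimated_progressive_infarct": 15, "reversible_perfusion_deficit": 28, "progressive_infarct": 26}
    },
    "mirror": {
      "hypoperfused": {"no_abnormality": 4, "underestimated_progressive_infarct": 0, "reversible_perfusion_deficit": 78, "progressive_infarct": 41},
      "core": {"no_abnormality": 46, "underestimated_progressive_infarct": 7, "reversible_perfusion_deficit": 36, "progressive_infarct": 34}
    },
    "isp": {
      "hypoperfused": {"no_abnormality": 0, "underestimated_progressive_infarct": 0, "reversible_perfusion_deficit": 82, "progressive_infarct": 41},
      "core": {"no_abnormality": 4, "underestimated_progressive_infarct": 4, "reversible_perfusion_deficit": 78, "progressive_infarct": 37}
    }
  }
}
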