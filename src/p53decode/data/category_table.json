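{
  "version": 1,
  "description": "Lookup from (mRNA dynamical class, protein dynamical class) to the category letter. Cells never reachable without additional feedback independent of the p53 input are starred. The whole not_induced column is one category (k), giving 11 categories in total.",
  "mrna_classes": ["osc_induced_both", "nonosc_induced_both", "rising_only", "osc_only"],
  "protein_classes": ["oscillatory", "rise_both", "rise_and_decrease", "rising_only", "osc_only", "not_induced"],
  "table": {
    "osc_induced_both": {
      "oscillatory": "a",
      "rise_both": "b",
      "rise_and_decrease": "c",
      "rising_only": "d",
      "osc_only": "h",
      "not_induced": "k"
    },
    "nonosc_induced_both": {
      "oscillatory": "unobserved*",
      "rise_both": "e",
      "rise_and_decrease": "f",
      "rising_only": "g",
      "osc_only": "unobserved*",
      "not_induced": "k"
    },
    "rising_only": {
      "oscillatory": "unobserved*",
      "rise_both": "unobserved*",
      "rise_and_decrease": "unobserved*",
      "rising_only": "j",
      "osc_only": "unobserved*",
      "not_induced": "k"
    },
    "osc_only": {
      "oscillatory": "unobserved*",
      "rise_both": "unobserved*",
      "rise_and_decrease": "unobserved*",
      "rising_only": "unobserved*",
      "osc_only": "i",
      "not_induced": "k"
    }
  },
  "mechanism_by_category": {
    "a": "simple_regulation",
    "b": "simple_regulation",
    "c": "activation_threshold_low",
    "d": "cffl_posttranscriptional",
    "e": "simple_regulation",
    "f": "activation_threshold_low",
    "g": "activation_threshold_medium",
    "h": "iffl",
    "i": "activation_threshold_low",
    "j": "cffl_transcriptional",
    "k": "activation_threshold_high",
    "unobserved*": "undetermined"
  }
}
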