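{
  "type": "object",
  "required": [
    "flow_ledger",
    "qc",
    "score_summaries",
    "instrument_table",
    "offspring_iq_table",
    "maternal_iq_table",
    "diabetes_contrast",
    "confounder_scan"
  ],
  "properties": {
    "flow_ledger": {"type": "array"},
    "qc": {
      "type": "object",
      "required": ["hwe_mothers", "hwe_children", "freq_comparison", "bonferroni"],
      "properties": {
        "freq_comparison": {"type": "array"},
        "bonferroni": {
          "type": "object",
          "required": ["alpha", "n_tests", "exact", "display"]
        }
      }
    },
    "score_summaries": {"type": "object"},
    "instrument_table": {"type": "array"},
    "offspring_iq_table": {"type": "array"},
    "maternal_iq_table": {"type": "array"},
    "diabetes_contrast": {
      "type": "object",
      "required": ["outcome", "exposure", "n", "beta", "se", "ci_low", "ci_high", "p_value"]
    }
  }
}
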