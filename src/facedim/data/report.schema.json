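{
  "schema": "facedim.report/1",
  "row_required": ["variable", "test", "statistic_name", "statistic", "p", "d", "d_lo", "d_hi", "masculinised"],
  "sections": {
    "validation": {
      "required": ["analysis", "mode", "rows", "n_significant_features"]
    },
    "sibling_comparison": {
      "required": ["analysis", "mode", "sex", "rows"]
    },
    "three_group": {
      "required": ["analysis", "mode", "sex", "F", "df_between", "df_within", "p"]
    }
  }
}
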