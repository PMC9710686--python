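{
  "schema_version": 1,
  "status_multipliers": {
    "standard_name": 1.0,
    "curated": 0.99858675,
    "synonym": 0.99,
    "former_name": 0.95
  },
  "penalties": {
    "space_dash_mismatch": 0.998,
    "cap_query_upper_ref_lower": 0.997,
    "cap_query_lower_ref_upper": 0.997,
    "cap_mixed": 0.99,
    "plural_dropped": 0.995,
    "unaligned": 0.9
  }
}
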