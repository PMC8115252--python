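{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "neonoci pipeline report",
  "type": "object",
  "required": ["config", "config_hash", "stages"],
  "properties": {
    "config": {"type": "object", "required": ["seed", "out_dir"]},
    "config_hash": {"type": "string"},
    "stages": {
      "type": "object",
      "required": ["simulate", "evoked", "rsn", "predict", "structfun"],
      "properties": {
        "simulate": {"type": "object", "required": ["seed", "n_local", "n_dhcp"]},
        "evoked": {"type": "object", "required": ["seed", "clusters", "template_tests", "effective_tests"]},
        "rsn": {"type": "object", "required": ["seed", "networks"]},
        "predict": {"type": "object", "required": ["seed", "metrics", "p_values"]},
        "structfun": {"type": "object", "required": ["seed", "n_tests", "confirmatory", "subset_percentile"]}
      }
    }
  }
}
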