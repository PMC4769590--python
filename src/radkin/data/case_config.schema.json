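{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CaseConfig",
  "type": "object",
  "required": ["label", "growth", "radio", "treatment"],
  "properties": {
    "label": {"type": "string"},
    "growth": {
      "type": "object",
      "required": ["v0_cm3", "td0_days", "theta"],
      "properties": {
        "v0_cm3": {"type": "number", "exclusiveMinimum": 0},
        "td0_days": {"type": "number", "exclusiveMinimum": 0},
        "theta": {"type": "number", "exclusiveMinimum": 0, "maximum": 1}
      }
    },
    "radio": {
      "type": "object",
      "required": ["alpha"],
      "properties": {
        "alpha": {"type": "number", "minimum": 0},
        "alpha_beta": {"type": "number", "exclusiveMinimum": 0, "default": 10.0},
        "t_star": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
        "t_m": {"type": "number", "exclusiveMinimum": 0, "default": 10.0}
      }
    },
    "treatment": {
      "type": "object",
      "required": ["dose_gy", "t_r_days", "t_cl_days"],
      "properties": {
        "dose_gy": {"type": "number", "minimum": 0},
        "t_r_days": {"type": "number", "minimum": 0},
        "tau_rad_days": {"type": "number", "exclusiveMinimum": 0, "default": 8.0},
        "t_cl_days": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "td_at_treatment_days": {"type": "number", "exclusiveMinimum": 0},
    "metadata": {"type": "object"}
  }
}
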