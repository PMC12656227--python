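{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tapagree analysis report",
  "type": "object",
  "required": [
    "schema_version",
    "orientation",
    "seed",
    "config",
    "validity",
    "aggregated",
    "trial_level",
    "power"
  ],
  "properties": {
    "schema_version": {"type": "integer"},
    "orientation": {"type": "string", "enum": ["imu_minus_video"]},
    "seed": {"type": ["integer", "null"]},
    "config": {"type": "object"},
    "validity": {
      "type": "object",
      "required": ["n_trials_total", "n_valid_trials", "excluded_trials"],
      "properties": {
        "n_trials_total": {"type": "integer"},
        "n_valid_trials": {"type": "integer"},
        "excluded_trials": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["subject_id", "hand", "trial_index", "reason"],
            "properties": {
              "subject_id": {"type": "string"},
              "hand": {"type": "string"},
              "trial_index": {"type": "integer"},
              "reason": {"type": "string"}
            }
          }
        }
      }
    },
    "aggregated": {
      "type": "object",
      "required": ["n_taps", "iti"],
      "properties": {
        "n_taps": {"$ref": "#/$defs/agreement"},
        "iti": {"$ref": "#/$defs/agreement"}
      }
    },
    "trial_level": {
      "type": "object",
      "required": ["n_taps", "iti"],
      "properties": {
        "n_taps": {"$ref": "#/$defs/mixed"},
        "iti": {"$ref": "#/$defs/mixed"}
      }
    },
    "power": {
      "type": "object",
      "required": ["rho0", "rho1", "alpha", "power_target", "k", "sidedness", "n_required", "achieved_power"],
      "properties": {
        "rho0": {"type": "number"},
        "rho1": {"type": "number"},
        "alpha": {"type": "number"},
        "power_target": {"type": "number"},
        "k": {"type": "integer"},
        "sidedness": {"type": "string", "enum": ["one", "two"]},
        "n_required": {"type": "integer"},
        "n_subjects": {"type": "integer"},
        "achieved_power": {"type": "number"}
      }
    }
  },
  "$defs": {
    "loa": {
      "type": "object",
      "required": ["variant", "bias", "loa_low", "loa_high", "ci_bias", "ci_loa_low", "ci_loa_high", "rpc"],
      "properties": {
        "variant": {"type": "string", "enum": ["parametric", "nonparametric"]},
        "bias": {"type": "number"},
        "loa_low": {"type": "number"},
        "loa_high": {"type": "number"},
        "ci_bias": {"type": "array", "items": {"type": "number"}},
        "ci_loa_low": {"type": "array", "items": {"type": "number"}},
        "ci_loa_high": {"type": "array", "items": {"type": "number"}},
        "rpc": {"type": "number"}
      }
    },
    "agreement": {
      "type": "object",
      "required": [
        "variable",
        "n_units",
        "normality_p",
        "method_selected",
        "bias",
        "loa_low",
        "loa_high",
        "rpc",
        "parametric",
        "nonparametric",
        "slope",
        "slope_p",
        "icc",
        "icc_ci"
      ],
      "properties": {
        "variable": {"type": "string"},
        "n_units": {"type": "integer"},
        "normality_stat": {"type": ["number", "null"]},
        "normality_p": {"type": ["number", "null"]},
        "method_selected": {"type": "string", "enum": ["parametric", "nonparametric"]},
        "bias": {"type": "number"},
        "loa_low": {"type": "number"},
        "loa_high": {"type": "number"},
        "rpc": {"type": "number"},
        "parametric": {"$ref": "#/$defs/loa"},
        "nonparametric": {"$ref": "#/$defs/loa"},
        "slope": {"type": "number"},
        "slope_p": {"type": ["number", "null"]},
        "icc": {"type": "number"},
        "icc_ci": {"type": "array", "items": {"type": "number"}}
      }
    },
    "mixed": {
      "type": "object",
      "required": [
        "mean_bias",
        "intercept",
        "slope",
        "slope_p",
        "sigma_subject",
        "sigma_resid",
        "n_trials_used",
        "n_subjects"
      ],
      "properties": {
        "mean_bias": {"type": "number"},
        "intercept": {"type": "number"},
        "slope": {"type": "number"},
        "slope_p": {"type": ["number", "null"]},
        "sigma_subject": {"type": "number"},
        "sigma_resid": {"type": "number"},
        "n_trials_used": {"type": "integer"},
        "n_subjects": {"type": "integer"},
        "degenerate": {"type": "boolean"},
        "note": {"type": "string"}
      }
    }
  }
}
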