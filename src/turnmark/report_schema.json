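{
  "type": "object",
  "required": ["attempt_id", "skipped", "warnings", "n_visits", "n_days"],
  "properties": {
    "attempt_id": {"type": "string"},
    "skipped": {"type": "boolean"},
    "skip_reason": {"type": "string"},
    "warnings": {"type": "array", "items": {"type": "string"}},
    "n_visits": {"type": "integer"},
    "n_days": {"type": "integer"},
    "carer_set": {
      "type": "object",
      "required": ["c", "carers", "excluded"],
      "properties": {
        "c": {"type": "integer"},
        "carers": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["carer_id", "visit_count", "carer_class"],
            "properties": {
              "carer_id": {"type": "string"},
              "visit_count": {"type": "integer"},
              "carer_class": {"type": "string"},
              "helper_rank": {"type": ["integer", "null"]},
              "terminal": {"type": "boolean"}
            }
          }
        },
        "excluded": {"type": "array"}
      }
    },
    "validity": {
      "type": "object",
      "required": ["valid", "c", "warnings"],
      "properties": {
        "valid": {"type": "boolean"},
        "c": {"type": "integer"},
        "warnings": {"type": "array"}
      }
    },
    "proportion_alternated": {
      "type": "object",
      "required": ["proportion", "n_alt", "n_rep"],
      "properties": {
        "proportion": {"type": ["number", "null"]},
        "n_alt": {"type": "integer"},
        "n_rep": {"type": "integer"}
      }
    },
    "runs_test": {
      "type": "object",
      "required": ["R_obs", "E_R", "p", "alternative", "method"],
      "properties": {
        "R_obs": {"type": "integer"},
        "E_R": {"type": "number"},
        "Var_R": {"type": "number"},
        "z": {"type": ["number", "null"]},
        "p": {"type": "number"},
        "alternative": {"type": "string"},
        "method": {"type": "string"},
        "degenerate": {"type": "boolean"}
      }
    },
    "models": {
      "type": "object",
      "required": ["full", "per_individual", "pooled"],
      "properties": {
        "full": {"type": "object", "required": ["logLik", "n_params"]},
        "per_individual": {"type": "object", "required": ["logLik", "n_params"]},
        "pooled": {"type": "object", "required": ["logLik", "n_params"]}
      }
    },
    "lrt": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["general", "constrained", "stat", "df", "p"],
        "properties": {
          "general": {"type": "string"},
          "constrained": {"type": "string"},
          "stat": {"type": "number"},
          "df": {"type": "integer"},
          "p": {"type": "number"}
        }
      }
    },
    "turn_taking": {
      "type": "object",
      "required": ["carers", "per_carer", "group_ratio"],
      "properties": {
        "carers": {"type": "array"},
        "group_ratio": {"type": ["number", "string", "null"]},
        "pooled_ratio": {"type": ["number", "null"]}
      }
    },
    "wilcoxon_lambda_mu": {"type": "object"},
    "reciprocity": {"type": "object"},
    "ivi_summaries": {
      "type": "object",
      "required": ["per_carer", "group"],
      "properties": {
        "per_carer": {"type": "object"},
        "group": {"type": "object"}
      }
    },
    "ordering": {
      "type": "object",
      "required": ["p_scores", "mean", "sd"],
      "properties": {
        "p_scores": {"type": "array"},
        "mean": {"type": ["number", "null"]},
        "sd": {"type": ["number", "null"]}
      }
    },
    "randomization": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["statistic", "observed", "p_active", "passive_flag", "n_reps"],
        "properties": {
          "statistic": {"type": "string"},
          "observed": {"type": ["number", "string"]},
          "p_active": {"type": "number"},
          "passive_flag": {"type": "boolean"},
          "reference": {"type": ["number", "string"]},
          "n_reps": {"type": "integer"}
        }
      }
    },
    "bout_test": {"type": ["object", "null"]},
    "filter_report": {"type": "object"}
  }
}
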