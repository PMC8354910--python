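{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "restdecode experiment report",
  "type": "object",
  "required": ["config", "created_unix", "records", "summary"],
  "properties": {
    "config": {"type": "object"},
    "created_unix": {"type": "number"},
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "subject",
          "seed_entropy",
          "loo_cv_accuracy",
          "sd_rs_raw",
          "sd_rs_corrected",
          "critical_value",
          "empirical_p",
          "significant",
          "alpha"
        ],
        "properties": {
          "subject": {"type": "integer"},
          "seed_entropy": {"type": "array", "items": {"type": "integer"}},
          "loo_cv_accuracy": {"type": "number"},
          "realized_overlap": {"type": "number"},
          "n_trials": {"type": "integer"},
          "sd_rs_raw": {"type": "number"},
          "sd_rs_corrected": {"type": "number"},
          "critical_value": {"type": "number"},
          "empirical_p": {"type": "number"},
          "significant": {"type": "boolean"},
          "alpha": {"type": "number"}
        }
      }
    },
    "summary": {
      "type": "object",
      "required": [
        "n_subjects",
        "mean_accuracy",
        "mean_sd_rs_corrected",
        "significant_fraction"
      ],
      "properties": {
        "n_subjects": {"type": "integer"},
        "mean_accuracy": {"type": "number"},
        "sd_accuracy": {"type": "number"},
        "mean_sd_rs_corrected": {"type": "number"},
        "significant_fraction": {"type": "number"}
      }
    }
  }
}
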