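{
  "$comment": "Layout of economics.yaml. Validation is performed by chwcea.params.load_parameters; this document describes the expected structure.",
  "type": "object",
  "required": ["disability_weights", "budget_items", "economy", "thresholds"],
  "properties": {
    "relapse_split_to_adherent": {
      "type": "number", "minimum": 0, "maximum": 1,
      "description": "Fraction of relapses from remission that return to the adherent state; the complement returns to nonadherent."
    },
    "disability_weights": {
      "type": "object",
      "required": ["untreated", "treated_seizure_free", "treated_with_seizures", "adherent_seizure_free_share"],
      "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
    },
    "budget_items": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "number", "minimum": 0}],
        "description": "[label, annual ZAR amount]"
      }
    },
    "economy": {
      "type": "object",
      "required": ["exchange_rate_zar_per_intl_dollar", "gdp_per_capita_intl_dollar"],
      "properties": {
        "exchange_rate_zar_per_intl_dollar": {"type": "number", "exclusiveMinimum": 0},
        "gdp_per_capita_intl_dollar": {"type": "number", "exclusiveMinimum": 0},
        "working_days_per_year_for_daily_gdp": {"type": "integer", "minimum": 1},
        "mortality_multiplier_nonadherent": {"type": "number", "exclusiveMinimum": 0},
        "mortality_multiplier_adherent": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "thresholds": {
      "type": "object",
      "required": ["wtp_intl_dollar", "gdp_threshold_intl_dollar"],
      "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
    }
  }
}
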