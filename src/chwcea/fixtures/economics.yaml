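# Scalar model parameters: disability weights, program budget, economic
# constants and cost-effectiveness thresholds.  Layout documented in
# config_schema.json.
relapse_split_to_adherent: 0.5

disability_weights:
  untreated: 0.42
  treated_seizure_free: 0.072
  treated_with_seizures: 0.319
  adherent_seizure_free_share: 0.60

# Itemized annual intervention budget for one sub-district, ZAR per annum.
budget_items:
  - ["4 Community Health Workers", 240000]
  - ["1 Program Coordinator", 400000]
  - ["Trainer salary", 5000]
  - ["Room & equipment rental", 500]
  - ["Cell phone & airtime", 5000]
  - ["Stationary", 3000]
  - ["Pamphlets", 2500]
  - ["Local transport", 8320]

economy:
  exchange_rate_zar_per_intl_dollar: 5.39
  gdp_per_capita_intl_dollar: 13215
  working_days_per_year_for_daily_gdp: 365
  # epilepsy mortality = multiplier x published cohort mortality
  mortality_multiplier_nonadherent: 2.5
  mortality_multiplier_adherent: 0.5

thresholds:
  wtp_intl_dollar: 2154
  gdp_threshold_intl_dollar: 13215
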