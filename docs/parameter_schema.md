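# Parameter file schema

One YAML document. All probabilities are annual; all monetary values are
GBP at 2019 prices. `quitcost generate` writes the packaged synthetic
defaults; `quitcost.params.load_parameters` validates every invariant on
load and raises a schema error (missing/unknown field, named) or a
validation error (invariant broken, with path and offending value).

Stratum keys combine sex and age band: `male_18_34`, `male_35_64`,
`male_65_plus`, `female_18_34`, `female_35_64`, `female_65_plus`.

```yaml
strata:                      # exactly the six sex × age-band cells
  - sex: male                # male | female
    age_band: "18-34"        # 18-34 | 35-64 | 65+
    cohort_share: 0.15       # shares sum to 1 across strata
    all_cause_mortality: 0.0008

diseases:                    # exactly: copd, lung_cancer, chd, stroke, asthma
  copd:
    incidence:               # never-smoker reference, per stratum key
      male_18_34: 0.0001
      # ... all six keys
    prevalence:              # smoking-cohort starting prevalence
      male_18_34: 0.001
      # ...
    excess_mortality:        # never-smoker reference, per stratum key
      male_18_34: 0.003
      # ...
    rr_smoker: 10.0          # risk ratios scale incidence and excess
    rr_recent_quitter: 9.0   #   mortality by smoking status
    rr_long_quitter: 4.0
    annual_cost: 1150.0      # GBP per person-year in the disease state
    utility_value: 0.75      # per-year utility weight in [0, 1]

baseline_risks:              # one-year probabilities on standard-dose NRT
  p_abstain_nrt_std: 0.212
  p_depression_nrt_std: 0.0775   # 8274 / 106,759
  p_selfharm_nrt_std: 0.00506    # 540 / 106,759

relapse:                     # annual, by years since quitting
  p_relapse_short: 0.13      # < 5 years
  p_relapse_long: 0.03       # 5–10 years
  p_relapse_10plus: 0.0009   # ≥ 10 years (must be non-increasing)

adverse_events:
  disutility_depression: 0.20    # one-off QALY decrement
  cost_depression: 1000.0        # one-off GBP
  disutility_selfharm: 0.15      # nonfatal
  cost_selfharm: 2500.0          # nonfatal
  fatal_fraction_selfharm: 0.05  # share of self-harm events that are fatal

economics:
  discount_rate: 0.035
  wtp: 20000.0               # willingness-to-pay, GBP per QALY
  population_per_year: 274021
  cohort_size: 10000
  psa_draws: 5000
  horizon: 100               # maximum simulated age
  baseline_utility:          # disease-free smoker utility, per stratum key
    male_18_34: 0.93
    # ...

course_costs:                # one-off GBP, all 14 intervention ids
  nrt_low: 100.0
  nrt_std: 160.0
  # ... nrt_high, bupropion_low, bupropion_std, varenicline_low,
  #     varenicline_std, ecig_low, ecig_high, bupropion_std_nrt_high,
  #     varenicline_low_nrt_std, varenicline_std_nrt_std,
  #     varenicline_std_nrt_high, varenicline_std_bupropion_std

relative_effects:            # one realized slice, log odds ratios vs nrt_std
  log_or_abstinence:         # all 14 ids; nrt_std must be exactly 0
    nrt_std: 0.0
    ecig_low: 0.55
    # ...
  log_or_mane:               # null where no observed MANE evidence
    nrt_std: 0.0
    nrt_low: null            # inherits a donor via the harm map
    # ...
```
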