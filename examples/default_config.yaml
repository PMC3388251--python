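# cfscreen run configuration (annotated defaults).
# Probabilities may be decimals or rational strings such as "1/30".

population:
  cohort_size: 200000        # newborns to simulate
  seed: 0                   # root seed; all randomness derives from it
  # P(non-classical | two disease alleles); assumption, not a published value
  fraction_non_classical_given_cf: 0.28
  # 4 meconium-ileus diagnoses per 29 CF births per year
  meconium_ileus_rate_given_cf: "4/29"
  strata:                   # fractions must sum to 1
    - name: dutch_general
      fraction_of_births: 0.90
      carrier_frequency: "1/30"
      panel_detectability: 0.95   # assumption: panel covers "all common" mutations
    - name: turkish
      fraction_of_births: 0.05
      carrier_frequency: "1/50"
      panel_detectability: 0.44   # published panel sensitivity, Turkish ancestry
    - name: north_african
      fraction_of_births: 0.05
      carrier_frequency: "1/50"
      panel_detectability: 0.69   # published panel sensitivity, North African ancestry

biomarkers:
  # The unaffected IRT log-normal is solved from these two published
  # population quantiles; everything else is a documented default.
  irt_tail_constraints:
    - {threshold_ugl: 50.0, exceedance_probability: 0.0243}
    - {threshold_ugl: 60.0, exceedance_probability: 0.0103}
  carrier_irt_median_ratio: 1.15  # carriers run mildly elevated IRT
  log_correlation: 0.0            # IRT-PAP log-scale correlation within class
  classes:                        # medians in ug/l, sigmas on the log scale
    CLASSICAL_CF:
      IRT: {median_ugl: 130.0, sigma_log: 0.40}
      PAP: {median_ugl: 14.0, sigma_log: 0.60}
    NON_CLASSICAL_CF:
      IRT: {median_ugl: 105.0, sigma_log: 0.45}
      PAP: {median_ugl: 10.0, sigma_log: 0.60}
    UNAFFECTED:
      PAP: {median_ugl: 0.4, sigma_log: 0.85}
    CARRIER:
      PAP: {median_ugl: 0.4, sigma_log: 0.85}

protocol:                         # national four-step cutoffs, ug/l
  irt_cutoff_ugl: 60.0
  irt_high_ugl: 100.0
  pap_cutoff_mid_ugl: 3.0        # applies when 60 <= IRT < 100
  pap_cutoff_high_ugl: 1.6       # applies when IRT >= 100
  failsafe_enabled: true         # panel-negative + IRT>=100 + PAP>=1.6 -> sequencing
  carrier_reporting: true        # parents may opt out: set false
  ega_sensitivity: 1.0           # per-allele detection probability of sequencing
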