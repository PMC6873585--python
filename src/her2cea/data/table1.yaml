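# Canonical input parameter table for the Philippine cost-utility model of
# 1-year adjuvant trastuzumab + chemotherapy vs chemotherapy alone in
# HER2-positive early breast cancer. All costs in 2017 PHP. Transition
# probabilities are annual. SEs feed the PSA sampling distributions
# (beta for probabilities/utilities, gamma for costs, log-normal for ratios).
settings:
  discount_rate: 0.035
  horizon_cycles: 49
  efficacy_duration_years: 11
  threshold_php_per_qaly: 120000.0
  start_age: 50
parameters:
  # annual baseline transition probabilities
  - {name: tp_dfs_chf, mean: 0.0053, se: 0.0024, distribution: beta, role: transition_prob}
  - {name: tp_dfs_rec, mean: 0.0294, se: 0.0029, distribution: beta, role: transition_prob}
  - {name: tp_dfs_met, mean: 0.0785, se: 0.0140, distribution: beta, role: transition_prob}
  - {name: tp_dfs_death, mean: 0.0020, se: 0.0001, distribution: beta, role: transition_prob}
  - {name: tp_chf_rec, mean: 0.0294, se: 0.0029, distribution: beta, role: transition_prob}
  - {name: tp_chf_met, mean: 0.0785, se: 0.0140, distribution: beta, role: transition_prob}
  - {name: tp_chf_death, mean: 0.1500, se: 0.0153, distribution: beta, role: transition_prob}
  - {name: tp_rec_met, mean: 0.0785, se: 0.0140, distribution: beta, role: transition_prob}
  - {name: tp_rec_death, mean: 0.2950, se: 0.2066, distribution: beta, role: transition_prob}
  - {name: tp_met_death, mean: 0.2950, se: 0.2066, distribution: beta, role: transition_prob}
  # pooled relative treatment effects of adjuvant trastuzumab
  - {name: hr_dfs, mean: 0.65, se: 0.0825, distribution: lognormal, role: relative_effect}
  - {name: hr_os, mean: 0.67, se: 0.0493, distribution: lognormal, role: relative_effect}
  - {name: rr_chf, mean: 3.97, se: 0.2240, distribution: lognormal, role: relative_effect}
  # EQ-5D-3L health-state utilities
  - {name: u_dfs, mean: 0.832, se: 0.0084, distribution: beta, role: utility}
  # the published dispersion for the CHF utility is not usable as a beta SE;
  # the SE shared by the other state utilities is substituted (overridable)
  - {name: u_chf, mean: 0.670, se: 0.0262, distribution: beta, role: utility}
  - {name: u_rec, mean: 0.828, se: 0.0262, distribution: beta, role: utility}
  - {name: u_met, mean: 0.762, se: 0.0262, distribution: beta, role: utility}
  # one-off treatment-course costs (drugs, administration, cardiac monitoring)
  - {name: dmc_tx_trast, mean: 1076607, se: 54929, distribution: gamma, role: cost_dmc}
  - {name: dmc_tx_ct, mean: 194900, se: 9944, distribution: gamma, role: cost_dmc}
  - {name: dnmc_tx_trast, mean: 9432, se: 481, distribution: gamma, role: cost_dnmc}
  - {name: dnmc_tx_ct, mean: 3494, se: 178, distribution: gamma, role: cost_dnmc}
  # annual state costs
  - {name: dmc_dfs, mean: 9493, se: 484, distribution: gamma, role: cost_dmc}
  - {name: dnmc_dfs, mean: 1747, se: 80, distribution: gamma, role: cost_dnmc}
  - {name: dmc_chf, mean: 3400, se: 1602, distribution: gamma, role: cost_dmc}
  - {name: dnmc_chf, mean: 1049, se: 0, distribution: gamma, role: cost_dnmc}
  - {name: dmc_rec_y1, mean: 567156, se: 3061, distribution: gamma, role: cost_dmc}
  - {name: dnmc_rec_y1, mean: 8166, se: 1488, distribution: gamma, role: cost_dnmc}
  - {name: dmc_rec_later, mean: 182437, se: 15513, distribution: gamma, role: cost_dmc}
  - {name: dnmc_rec_later, mean: 17817, se: 178, distribution: gamma, role: cost_dnmc}
  # duplicate published "(after first year)" recurrence cost pair; unused
  # unless settings.recurrence_later_costs == "alternate"
  - {name: dmc_rec_later_alt, mean: 516904, se: 26373, distribution: gamma, role: cost_dmc}
  - {name: dnmc_rec_later_alt, mean: 5939, se: 273, distribution: gamma, role: cost_dnmc}
  - {name: dmc_met_y1, mean: 956172, se: 48784, distribution: gamma, role: cost_dmc}
  - {name: dnmc_met_y1, mean: 10131, se: 465, distribution: gamma, role: cost_dnmc}
  - {name: dmc_met_later, mean: 1666816, se: 59531, distribution: gamma, role: cost_dmc}
  - {name: dnmc_met_later, mean: 5939, se: 273, distribution: gamma, role: cost_dnmc}
  # drug-only acquisition price per treatment course (negotiated 150 mg vial price)
  - {name: trast_drug_cost_per_course, mean: 619667, se: 0, distribution: fixed, role: cost_dmc}
  # national epidemiology for the budget impact
  - {name: prevalent_bc, mean: 64046, se: 0, distribution: fixed, role: epidemiology}
  - {name: incident_bc, mean: 21057, se: 0, distribution: fixed, role: epidemiology}
  - {name: her2_rate, mean: 0.2317, se: 0, distribution: fixed, role: epidemiology}
  - {name: early_rate, mean: 0.80, se: 0, distribution: fixed, role: epidemiology}
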