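# First-line nivolumab + ipilimumab vs platinum-doublet chemotherapy,
# advanced NSCLC, PD-L1 expression < 1% (75.3/24.7 histology split,
# distinct adverse-event profile and subsequent-therapy mix).
# Survival time unit: 6-week model cycles.  Prices: USD per cycle
# (radiotherapy: USD per course).
population: pdl1_lt1
settings:
  cycle_length_days: 42.0
  horizon_years: 20.0
  annual_discount_rate: 0.03
  wtp: 150000.0
utilities:
  u_pfs_intervention: 0.784
  u_pfs_comparator: 0.693
  u_pd: 0.473
histology_nonsquamous: 0.753
platinum_carboplatin_share: 0.5
drug_prices:
  nivolumab: 17517.15
  ipilimumab: 10718.96
  pemetrexed: 12782.85
  gemcitabine: 92.0
  carboplatin: 56.55
  cisplatin: 51.78
  pembrolizumab: 19755.6
  post_study_nivolumab: 17517.15
  radiotherapy: 15899.24
  targeted_therapy: 12615.68
  subsequent_chemotherapy: 238.74
ae_costs:
  anemia: 7969.56
  neutropenia: 32995.0
  neutrophil_count_decreased: 32995.0
  fatigue: 0.0
  rash: 13376.0
  diarrhea: 10301.0
  decreased_appetite: 9711.0
  vomiting: 10301.0
  nausea: 10301.0
admin_cost_per_cycle: 139.61
ct_cost_per_cycle: 231.0
lab_cost_per_cycle: 315.0
intervention:
  name: nivolumab_ipilimumab
  regimen: nivo_ipi
  os:
    shape: 0.764844
    scale: 0.09826
  pfs:
    shape: 0.66247
    scale: 0.29319
  discontinuation: 0.519
  ae_profile:
  - name: diarrhea
    risk: 0.022
  - name: fatigue
    risk: 0.011
  - name: anemia
    risk: 0.137
  subsequent_mix:
  - name: radiotherapy
    proportion: 0.182
    price_key: radiotherapy
    accrual: one_time
  - name: chemotherapy
    proportion: 0.422
    price_key: subsequent_chemotherapy
  - name: targeted_therapy
    proportion: 0.064
    price_key: targeted_therapy
comparator:
  name: chemotherapy
  regimen: platinum_doublet
  os:
    shape: 1.023457
    scale: 0.085114
  pfs:
    shape: 1.19322
    scale: 0.16572
  discontinuation: 0.57
  ae_profile:
  - name: anemia
    risk: 0.137
  - name: neutropenia
    risk: 0.115
  - name: nausea
    risk: 0.027
  - name: fatigue
    risk: 0.022
  - name: decreased_appetite
    risk: 0.016
  - name: vomiting
    risk: 0.016
  - name: diarrhea
    risk: 0.011
  subsequent_mix:
  - name: radiotherapy
    proportion: 0.167
    price_key: radiotherapy
    accrual: one_time
  - name: chemotherapy
    proportion: 0.344
    price_key: subsequent_chemotherapy
  - name: post_study_nivolumab
    proportion: 0.301
    price_key: post_study_nivolumab
  - name: targeted_therapy
    proportion: 0.091
    price_key: targeted_therapy
sa_ranges:
  drug_prices.nivolumab:
    min: 14013.72
    max: 21020.58
    family: gamma
  drug_prices.ipilimumab:
    min: 8575.17
    max: 12862.75
    family: gamma
  drug_prices.pemetrexed:
    min: 10226.28
    max: 15339.42
    family: gamma
  drug_prices.gemcitabine:
    min: 73.6
    max: 110.4
    family: gamma
  drug_prices.carboplatin:
    min: 45.24
    max: 67.86
    family: gamma
  drug_prices.cisplatin:
    min: 41.42
    max: 62.14
    family: gamma
  drug_prices.post_study_nivolumab:
    min: 14013.72
    max: 21020.58
    family: gamma
  drug_prices.radiotherapy:
    min: 12719.39
    max: 19079.09
    family: gamma
  drug_prices.targeted_therapy:
    min: 10092.54
    max: 15138.82
    family: gamma
  drug_prices.subsequent_chemotherapy:
    min: 190.99
    max: 286.49
    family: gamma
  ae_costs.anemia:
    min: 6375.65
    max: 9536.47
    family: gamma
  ae_costs.neutropenia:
    min: 24746.0
    max: 41244.0
    family: gamma
  ae_costs.diarrhea:
    min: 8240.8
    max: 12361.2
    family: gamma
  ae_costs.decreased_appetite:
    min: 7768.8
    max: 11653.2
    family: gamma
  ae_costs.vomiting:
    min: 8240.8
    max: 12361.2
    family: gamma
  ae_costs.nausea:
    min: 8240.8
    max: 12361.2
    family: gamma
  admin_cost_per_cycle:
    min: 111.69
    max: 167.53
    family: gamma
  ct_cost_per_cycle:
    min: 208.0
    max: 254.0
    family: gamma
  lab_cost_per_cycle:
    min: 252.0
    max: 378.0
    family: gamma
  utilities.u_pfs_intervention:
    min: 0.74
    max: 0.828
    family: beta
  utilities.u_pfs_comparator:
    min: 0.642
    max: 0.743
    family: beta
  utilities.u_pd:
    min: 0.166
    max: 0.568
    family: beta
  intervention.ae_profile[diarrhea].risk:
    min: 0.0176
    max: 0.0264
    family: beta
  intervention.ae_profile[fatigue].risk:
    min: 0.0088
    max: 0.0132
    family: beta
  intervention.ae_profile[anemia].risk:
    min: 0.1096
    max: 0.1644
    family: beta
  comparator.ae_profile[anemia].risk:
    min: 0.1096
    max: 0.1644
    family: beta
  comparator.ae_profile[neutropenia].risk:
    min: 0.092
    max: 0.138
    family: beta
  comparator.ae_profile[nausea].risk:
    min: 0.0216
    max: 0.0324
    family: beta
  comparator.ae_profile[fatigue].risk:
    min: 0.0176
    max: 0.0264
    family: beta
  comparator.ae_profile[decreased_appetite].risk:
    min: 0.0128
    max: 0.0192
    family: beta
  comparator.ae_profile[vomiting].risk:
    min: 0.0128
    max: 0.0192
    family: beta
  comparator.ae_profile[diarrhea].risk:
    min: 0.0088
    max: 0.0132
    family: beta
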