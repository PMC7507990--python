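# First-line nivolumab + ipilimumab vs platinum-doublet chemotherapy,
# advanced NSCLC, PD-L1 expression >= 50%.
# Survival time unit: 6-week model cycles.  Prices: USD per cycle
# (radiotherapy: USD per course).
population: pdl1_ge50
settings:
  cycle_length_days: 42.0
  horizon_years: 20.0
  annual_discount_rate: 0.03
  wtp: 150000.0
utilities:
  u_pfs_intervention: 0.784
  u_pfs_comparator: 0.693
  u_pd: 0.473
histology_nonsquamous: 0.708
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
  os: {shape: 0.658678, scale: 0.112585}
  pfs: {shape: 0.53605, scale: 0.27369}
  discontinuation: 0.422
  ae_profile:
    - {name: rash, risk: 0.023}
    - {name: diarrhea, risk: 0.015}
    - {name: fatigue, risk: 0.02}
    - {name: decreased_appetite, risk: 0.01}
    - {name: anemia, risk: 0.013}
  subsequent_mix:
    - {name: radiotherapy, proportion: 0.174, price_key: radiotherapy, accrual: one_time}
    - {name: chemotherapy, proportion: 0.316, price_key: subsequent_chemotherapy}
    - {name: post_study_nivolumab, proportion: 0.04, price_key: post_study_nivolumab}
    - {name: targeted_therapy, proportion: 0.053, price_key: targeted_therapy}
comparator:
  name: chemotherapy
  regimen: platinum_doublet
  os: {shape: 0.868245, scale: 0.093252}
  pfs: {shape: 1.10045, scale: 0.17421}
  discontinuation: 0.625
  ae_profile:
    - {name: anemia, risk: 0.106}
    - {name: neutropenia, risk: 0.07}
    - {name: neutrophil_count_decreased, risk: 0.085}
    - {name: nausea, risk: 0.018}
    - {name: fatigue, risk: 0.01}
    - {name: decreased_appetite, risk: 0.01}
    - {name: vomiting, risk: 0.026}
  subsequent_mix:
    - {name: radiotherapy, proportion: 0.244, price_key: radiotherapy, accrual: one_time}
    - {name: chemotherapy, proportion: 0.275, price_key: subsequent_chemotherapy}
    - {name: post_study_nivolumab, proportion: 0.325, price_key: post_study_nivolumab}
    - {name: pembrolizumab, proportion: 0.081, price_key: pembrolizumab}
    - {name: targeted_therapy, proportion: 0.043, price_key: targeted_therapy}
sa_ranges:
  drug_prices.nivolumab: {min: 14013.72, max: 21020.58, family: gamma}
  drug_prices.ipilimumab: {min: 8575.17, max: 12862.75, family: gamma}
  drug_prices.pemetrexed: {min: 10226.28, max: 15339.42, family: gamma}
  drug_prices.gemcitabine: {min: 73.6, max: 110.4, family: gamma}
  drug_prices.carboplatin: {min: 45.24, max: 67.86, family: gamma}
  drug_prices.cisplatin: {min: 41.42, max: 62.14, family: gamma}
  drug_prices.pembrolizumab: {min: 15804.48, max: 23706.72, family: gamma}
  drug_prices.post_study_nivolumab: {min: 14013.72, max: 21020.58, family: gamma}
  drug_prices.radiotherapy: {min: 12719.39, max: 19079.09, family: gamma}
  drug_prices.targeted_therapy: {min: 10092.54, max: 15138.82, family: gamma}
  drug_prices.subsequent_chemotherapy: {min: 190.99, max: 286.49, family: gamma}
  ae_costs.anemia: {min: 6375.65, max: 9536.47, family: gamma}
  ae_costs.neutropenia: {min: 24746.0, max: 41244.0, family: gamma}
  ae_costs.neutrophil_count_decreased: {min: 24746.0, max: 41244.0, family: gamma}
  ae_costs.rash: {min: 10700.8, max: 16051.2, family: gamma}
  ae_costs.diarrhea: {min: 8240.8, max: 12361.2, family: gamma}
  ae_costs.decreased_appetite: {min: 7768.8, max: 11653.2, family: gamma}
  ae_costs.vomiting: {min: 8240.8, max: 12361.2, family: gamma}
  ae_costs.nausea: {min: 8240.8, max: 12361.2, family: gamma}
  admin_cost_per_cycle: {min: 111.69, max: 167.53, family: gamma}
  ct_cost_per_cycle: {min: 208.0, max: 254.0, family: gamma}
  lab_cost_per_cycle: {min: 252.0, max: 378.0, family: gamma}
  utilities.u_pfs_intervention: {min: 0.74, max: 0.828, family: beta}
  utilities.u_pfs_comparator: {min: 0.642, max: 0.743, family: beta}
  utilities.u_pd: {min: 0.166, max: 0.568, family: beta}
  intervention.ae_profile[rash].risk: {min: 0.0184, max: 0.0276, family: beta}
  intervention.ae_profile[diarrhea].risk: {min: 0.012, max: 0.018, family: beta}
  intervention.ae_profile[fatigue].risk: {min: 0.016, max: 0.024, family: beta}
  intervention.ae_profile[decreased_appetite].risk: {min: 0.008, max: 0.012, family: beta}
  intervention.ae_profile[anemia].risk: {min: 0.0104, max: 0.0156, family: beta}
  comparator.ae_profile[anemia].risk: {min: 0.0848, max: 0.1272, family: beta}
  comparator.ae_profile[neutropenia].risk: {min: 0.056, max: 0.084, family: beta}
  comparator.ae_profile[neutrophil_count_decreased].risk: {min: 0.068, max: 0.102, family: beta}
  comparator.ae_profile[nausea].risk: {min: 0.0144, max: 0.0216, family: beta}
  comparator.ae_profile[fatigue].risk: {min: 0.008, max: 0.012, family: beta}
  comparator.ae_profile[decreased_appetite].risk: {min: 0.008, max: 0.012, family: beta}
  comparator.ae_profile[vomiting].risk: {min: 0.0208, max: 0.0312, family: beta}
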