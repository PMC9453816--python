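# Base-case model inputs: second-/third-line therapy for driver-negative
# advanced or metastatic NSCLC in China, 2021 USD (1 USD = 6.4512 CNY; the
# conversion is metadata only, all values below are already USD).
#
# Every `{mean, low, high, distribution}` block is a RangedValue: the low/high
# columns are the deterministic-sensitivity sweep bounds (95% CI, +/-50% of
# baseline, or a guideline range) and the distribution tag selects the
# probabilistic-sensitivity sampling family ("fixed" = not sampled).
currency: USD_2021
cny_per_usd: 6.4512

settings:
  cycle_length_days: 21
  horizon_years: 30
  discount_rate_annual: {mean: 0.05, low: 0.0, high: 0.08, distribution: fixed}
  wtp_per_qaly: 35663
  body_weight_kg: {mean: 65.0, low: 32.5, high: 97.5, distribution: normal}
  body_surface_m2: {mean: 1.72, low: 0.86, high: 2.58, distribution: normal}
  utilities:
    pfs: {mean: 0.856, low: 0.718, high: 0.994, distribution: beta}
    pd: {mean: 0.768, low: 0.595, high: 0.941, distribution: beta}
    end_stage: {mean: 0.703, low: 0.545, high: 0.861, distribution: beta}
  care_costs:  # per 3-week cycle
    followup: {mean: 55.60, low: 27.80, high: 83.40, distribution: gamma}
    bsc: {mean: 337.50, low: 168.75, high: 506.25, distribution: gamma}
    palliative: {mean: 2627.80, low: 1313.90, high: 3941.70, distribution: gamma}
  anlotinib:  # third-/further-line therapy taken up by a share of PD patients
    os: {theta: 0.01184, kappa: 1.69854}
    pfs: {theta: 0.01411, kappa: 2.18608}
    dosing:
      unit_price: {mean: 665.92, low: 332.96, high: 998.88, distribution: gamma}
      unit_size: 168.0
      dose_kind: per_cycle_pack
      dose_value: 168.0
      administrations_per_cycle: 1.0
  half_cycle_correction: false
  end_stage_mortality_mode: anlotinib_os   # or: fixed (+ end_stage_fixed_prob)
  end_stage_fixed_prob: null
  palliative_cost_mode: one_time           # or: per_cycle | one_time_at_death
  pd_clock_mode: state_entry               # or: model_time

strategies:
  - name: docetaxel
    os: {theta: 0.01092, kappa: 1.61683}
    pfs: {theta: 0.05747, kappa: 1.96409}
    discontinuation_prob_per_cycle:
      {mean: 0.007759, low: 0.003880, high: 0.011639, distribution: beta}
    dosing:
      unit_price: {mean: 39.53, low: 19.76, high: 59.29, distribution: gamma}
      unit_size: 75.0        # mg per vial
      dose_kind: per_m2
      dose_value: 75.0       # mg/m2 once per cycle
      administrations_per_cycle: 1.0
    ae_cost: {mean: 1212.99, low: 606.50, high: 1819.49, distribution: gamma}
    ae_disutility: {mean: 0.061, low: 0.030, high: 0.091, distribution: beta}
    subsequent_therapy_proportion:
      {mean: 0.626, low: 0.313, high: 0.939, distribution: beta}

  - name: tislelizumab
    os: {theta: 0.00927, kappa: 1.46070}
    pfs: {theta: 0.09158, kappa: 1.28272}
    discontinuation_prob_per_cycle:
      {mean: 0.004499, low: 0.002249, high: 0.006748, distribution: beta}
    dosing:
      unit_price: {mean: 675.84, low: 337.92, high: 1013.76, distribution: gamma}
      unit_size: 200.0
      dose_kind: flat
      dose_value: 200.0      # 200 mg once per 3-week cycle
      administrations_per_cycle: 1.0
    ae_cost: {mean: 89.36, low: 44.68, high: 134.04, distribution: gamma}
    ae_disutility: {mean: 0.002, low: 0.001, high: 0.003, distribution: beta}
    subsequent_therapy_proportion:
      {mean: 0.497, low: 0.249, high: 0.746, distribution: beta}

  - name: nivolumab
    # No head-to-head trial: survival is derived from the tislelizumab
    # log-logistic curves through network-meta-analysis hazard ratios.
    os:
      reference: tislelizumab
      endpoint: os
      hr: {mean: 1.170, ci_low: 0.509, ci_high: 2.683}
    pfs:
      reference: tislelizumab
      endpoint: pfs
      hr: {mean: 1.235, ci_low: 0.540, ci_high: 2.844}
    discontinuation_prob_per_cycle:
      {mean: 0.003408, low: 0.001704, high: 0.005112, distribution: beta}
    dosing:
      unit_price: {mean: 43.02, low: 21.51, high: 64.52, distribution: gamma}
      unit_size: 3.0         # priced per 3 mg
      dose_kind: per_kg
      dose_value: 3.0        # 3 mg/kg every 2 weeks
      administrations_per_cycle: 1.5
    ae_cost: {mean: 13.39, low: 6.70, high: 20.09, distribution: gamma}
    ae_disutility: {mean: 0.002, low: 0.001, high: 0.003, distribution: beta}
    subsequent_therapy_proportion:
      {mean: 0.450, low: 0.225, high: 0.675, distribution: beta}

# Sex-specific scenarios. Only the nivolumab-vs-tislelizumab OS hazard ratios
# are published; a sex-specific tislelizumab-vs-docetaxel contrast must be
# supplied by the user before the male/female docetaxel comparison is
# meaningful, so these scenarios only re-specify the nivolumab arm.
scenarios:
  male:
    nivolumab.hr_os: {mean: 1.342, ci_low: 0.469, ci_high: 2.839}
  female:
    nivolumab.hr_os: {mean: 0.740, ci_low: 0.370, ci_high: 1.484}
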