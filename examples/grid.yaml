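# Example scenario grid. Every value shown is the shipped default unless
# noted; replace unit costs, decrements and distributions with local data.
inflation_factor: 1.0
arms: [standard, prioritize, triage_and_prioritize]

econ:
  discount_rate: 0.035
  wtp: 20000
  accrual: uniform        # or "lump" with lump_year
  horizon_years: 10

costs:                    # 2022 GBP; synthetic placeholders
  gp-consult: 39.00
  psa-test: 5.00
  pinpoint-test: 35.20
  triage-appt: 170.00
  mpmri: 250.00
  trus-biopsy: 450.00
  mdt: 110.00
  cystoscopy: 390.00
  ultrasound: 55.00
  x-ray: 30.00
# or: cost_csv: costs.csv            (header: step,unit_cost,ref_year)
# and: decrement_csv: decrements.csv (header: subtype,age_band,delay_months,ly_lost)

scenarios:
  - label: prostate-highvol-poor
    model: prostate
    volume_level: high
    performance_level: poor
    target_tww: 0.70      # capacity calibrated to this standard-care compliance
    cohort:
      annual_referrals: 7200
      prevalence: 0.169
      prostate_share: 0.7591
      bladder_share_of_bk: 0.5979
      risk_matrix:
        cancer: [0.87, 0.10, 0.03]      # P(low | cancer) = 0.03 anchored
        no_cancer: [0.05, 0.70, 0.25]
    cascade:
      mpmri_pos_nocancer: 0.35
    excess:               # additional waiting days beyond the 14-day window
      support: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16]
      probs: [0.205793, 0.164634, 0.131707, 0.105366, 0.084293, 0.067434,
              0.053947, 0.043158, 0.034526, 0.027621, 0.022097, 0.017677,
              0.014142, 0.011314, 0.009051, 0.007241]

  - label: bk-lowvol-high
    model: bladder_kidney
    volume_level: low
    performance_level: high
    target_tww: 0.90
    cohort:
      annual_referrals: 2000
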