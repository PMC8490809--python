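# Demo pipeline configuration: small synthetic worlds for both data sources.
# The index drug carries a 10x event-reporting multiplier; the co-drug a
# protective 0.2x interaction in reports and a 0.4x hazard multiplier in
# claims.
seed: 1
outdir: results/demo
reports:
  simulate:
    n_reports: 20000
claims:
  simulate:
    n_patients: 20000
analysis:
  index_drug: amiodarone
  codrug: dabigatran
  event_codes: [J704, J841, J849]
  run_in_months: 3
  window_months: 36
  min_cases: 3
  horizon_months: 36
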