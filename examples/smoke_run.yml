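# Minute-scale demonstration run on the synthetic basin.
# The default (unset) values reproduce the full leatherback study setup:
# 5000 agents, 18 years, the published species constants.
forcing:
  synthetic:
    lon_max: 200.0
    step: 2.0
    period_days: 120
release:
  n: 50
  start: 2000-06-01
  end: 2000-08-31
  peak: 2000-07-15
  sigma_days: 20
  box_center: [137.0, 13.5]
mode: active
years: 2
seed: 7
output:
  directory: out
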