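# Default study scenario: four building-type x compound strata with the
# published group summaries, a truncated-normal occupant time-use model,
# and a 5,000-trial Monte Carlo exposure simulation.
seed: 20131105
n_trials: 5000
strata:
  - building_type: dwelling
    compound: formaldehyde
    n: 383
    mean: 131.0
    sd: 90.0
    median: 100.0
  - building_type: office
    compound: formaldehyde
    n: 406
    mean: 85.0
    sd: 56.0
    median: 74.0
  - building_type: dwelling
    compound: benzene
    n: 379
    mean: 17.0
    sd: 16.0
    median: 11.0
  - building_type: office
    compound: benzene
    n: 375
    mean: 30.0
    sd: 34.0
    median: 16.0
time_use:
  mean_home: 0.657
  sd_home: 0.05
  mean_office: 0.176
  sd_office: 0.04
  cap: 0.95
decay:
  formaldehyde: 0.35
  benzene: 0.25
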