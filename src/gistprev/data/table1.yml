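# Default model parameters: UK unresectable/metastatic GIST prevalence model.
# Each entry: base value, standard error, one-way SA min-max range, and the
# sampling family used in probabilistic sensitivity analysis.
# Rates are per year; incidence is per person-year; p_resectable is a proportion.
incidence:
  base: 1.053e-5
  se: 1.39e-6
  min: 0.52e-5
  max: 1.50e-5
  family: gamma
p_resectable:
  base: 0.8
  se: 0.05
  min: 0.50
  max: 0.90
  family: beta
relapse_rate:
  base: 0.0464
  se: 0.0025
  min: 0.029
  max: 0.186
  family: gamma
imatinib_failure_rate:
  base: 0.351
  se: 0.103
  min: 0.205
  max: 0.645
  family: gamma
sunitinib_failure_rate:
  base: 0.974
  se: 0.085
  min: 0.533
  max: 1.435
  family: gamma
thirdline_exit_rate:
  base: 0.904
  se: 0.10
  min: 0.439
  max: 1.066
  family: gamma
background_mortality:
  base: 0.0314
  se: 0.0023
  min: 0.0269
  max: 0.0359
  family: gamma
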