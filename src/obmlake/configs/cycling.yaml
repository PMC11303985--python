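chlorophyll_per_biomass: 10.0
forcing:
  light:
    amplitude: 0.45
    floor: 0.0
    mean: 0.5
    phase: 81.0
  load:
    amplitude: 0.01
    floor: 0.0
    mean: 0.02
    phase: 20.0
  temperature:
    amplitude: 9.0
    floor: 0.0
    mean: 11.0
    phase: 113.0
initial: {}
lower:
  benthos_a: 0.5
  benthos_i_max: 0.1
  benthos_k: 3.0
  benthos_mort: 0.01
  benthos_q10: 2.0
  benthos_resp: 0.01
  flush: 0.002
  mineralization: 0.01
  mineralization_q10: 2.0
  phyto_k_n: 0.1
  phyto_loss: 0.04
  phyto_mu_max: 1.2
  phyto_q10: 1.9
  phyto_resp: 0.06
  zoo_a: 0.7
  zoo_i_max: 0.6
  zoo_k: 0.5
  zoo_mort: 0.03
  zoo_q10: 2.2
  zoo_resp: 0.08
omnivore:
  f_veg: 1.0
  i_max_ref: 0.12
  m_nat: 0.002
  obm: false
  prey:
  - a: 0.7
    c: 0.5
    f_gut: 1.0
    mode: pelagic
    pool: zooplankton
  - a: 0.6
    c: 0.3
    f_gut: 1.0
    mode: benthic
    pool: zoobenthos
  - a: 0.3
    c: 0.05
    f_gut: 4.0
    mode: benthic
    pool: sediment_pom
  q10: 2.0
  tradeoff:
    f_fc: 1.0
    f_pm: 1.0
    f_rf: 0.5
  u_ref: 0.008
predator:
  f_veg: 1.0
  i_max_ref: 0.03
  m_nat: 0.004
  obm: false
  prey:
  - a: 0.7
    c: 0.3
    f_gut: 1.0
    mode: piscivorous
    pool: omnivore
  q10: 2.0
  tradeoff:
    f_fc: 1.0
    f_pm: 1.0
    f_rf: 0.5
  u_ref: 0.004
run:
  analysis_fraction: 0.5
  dt: 1.0
  load_scale: 1.0
  seed: 0
  years: 100
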