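# Six-parameter flow screening space at the announced ranges.
parameters:
  - {name: equiv, type: continuous, low: 1.0, high: 3.0, units: equiv, precision: 0.1}
  - {name: tfoh_mol_pct, type: continuous, low: 0.5, high: 2.0, units: "mol%", precision: 0.01}
  - {name: temp_c, type: continuous, low: 20.0, high: 60.0, units: "°C", precision: 5.0}
  - {name: conc_m, type: continuous, low: 0.01, high: 0.1, units: M, precision: 0.001}
  - {name: flow_ml_min, type: continuous, low: 0.05, high: 0.2, units: mL/min, precision: 0.001}
  - {name: mixer, type: categorical, choices: [comet_x, beta_type, t_shaped]}
mixers:
  - {name: comet_x, volume_mL: 2.4}
  - {name: beta_type, volume_mL: 2.7}
  - {name: t_shaped, volume_mL: 1.6}
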