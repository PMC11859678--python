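# Dose grid for the dose-equivalence comparison, with PK chain enabled.
name: figure5_dose_equivalence
scenarios:
  - {bevacizumab_dose: 0.5}
  - {bevacizumab_dose: 5.0}
  - {oxaliplatin_dose_um: 160}
  - {oxaliplatin_dose_um: 180}
  - {oxaliplatin_dose_um: 200}
  - {oxaliplatin_dose_um: 220}
  - {oxaliplatin_dose_um: 240}
  - {oxaliplatin_dose_um: 260}
  - {oxaliplatin_dose_um: 280}
  - {oxaliplatin_dose_um: 300}
  - {oxaliplatin_dose_um: 320}
setups: [1]
with_pk: true
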