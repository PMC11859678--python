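# Organ sweep: control vs bevacizumab arms, both catheter setups.
name: figure3_organ_sweep
scenarios:
  - {bevacizumab_dose: 0.0}
  - {bevacizumab_dose: 0.5}
  - {bevacizumab_dose: 5.0}
setups: [1, 2]
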