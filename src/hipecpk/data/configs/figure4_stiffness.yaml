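# Collagen-fiber-density presets at the intestine site.
name: figure4_stiffness
scenarios:
  - {bevacizumab_dose: 0.0, collagen_density: low}
  - {bevacizumab_dose: 0.0, collagen_density: high}
  - {bevacizumab_dose: 0.5, collagen_density: low}
  - {bevacizumab_dose: 0.5, collagen_density: high}
  - {bevacizumab_dose: 5.0, collagen_density: low}
  - {bevacizumab_dose: 5.0, collagen_density: high}
organs: [Intestine]
setups: [1]
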