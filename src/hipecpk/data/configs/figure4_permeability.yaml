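# Microvascular-permeability sweep (0.2x to 5x baseline Pc) at the
# intestine site; only the 5 mg/kg arm (the low dose leaves Pc unchanged).
name: figure4_permeability
scenarios:
  - {bevacizumab_dose: 0.0, permeability_multiplier: 0.2}
  - {bevacizumab_dose: 5.0, permeability_multiplier: 0.2}
  - {bevacizumab_dose: 0.0, permeability_multiplier: 0.5}
  - {bevacizumab_dose: 5.0, permeability_multiplier: 0.5}
  - {bevacizumab_dose: 0.0, permeability_multiplier: 1.0}
  - {bevacizumab_dose: 5.0, permeability_multiplier: 1.0}
  - {bevacizumab_dose: 0.0, permeability_multiplier: 2.0}
  - {bevacizumab_dose: 5.0, permeability_multiplier: 2.0}
  - {bevacizumab_dose: 0.0, permeability_multiplier: 5.0}
  - {bevacizumab_dose: 5.0, permeability_multiplier: 5.0}
organs: [Intestine]
setups: [1]
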