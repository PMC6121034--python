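# GABA-evoked activation of the alpha1-F64A (alanine) mutant: flipping
# impairment intermediate between the leucine and cysteine mutants.
# Calibrated values.
name: glig_ala
ligands: [GABA]
states:
  - {name: R,    class: closed}
  - {name: AR,   class: closed, bound: {GABA: 1}}
  - {name: A2R,  class: closed, bound: {GABA: 2}}
  - {name: A2F,  class: flipped, bound: {GABA: 2}}
  - {name: A2O,  class: open, conductance_weight: 1.0, bound: {GABA: 2}}
  - {name: A2D,  class: desensitized, bound: {GABA: 2}}
  - {name: A2Dp, class: desensitized, bound: {GABA: 2}}
transitions:
  - {from: R,    to: AR,   rate_name: kon1,  base_value: 2.0e+7, ligand: GABA, order: 1}
  - {from: AR,   to: R,    rate_name: koff1, base_value: 1540.0}
  - {from: AR,   to: A2R,  rate_name: kon2,  base_value: 1.0e+7, ligand: GABA, order: 1}
  - {from: A2R,  to: AR,   rate_name: koff2, base_value: 3080.0}
  - {from: A2R,  to: A2F,  rate_name: delta, base_value: 180.0}
  - {from: A2F,  to: A2R,  rate_name: gamma, base_value: 900.0}
  - {from: A2F,  to: A2O,  rate_name: beta,  base_value: 8000.0}
  - {from: A2O,  to: A2F,  rate_name: alpha, base_value: 400.0}
  - {from: A2F,  to: A2D,  rate_name: d,     base_value: 500.0}
  - {from: A2D,  to: A2F,  rate_name: r,     base_value: 130.0}
  - {from: A2F,  to: A2Dp, rate_name: dp,    base_value: 40.0}
  - {from: A2Dp, to: A2F,  rate_name: rp,    base_value: 0.02}
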