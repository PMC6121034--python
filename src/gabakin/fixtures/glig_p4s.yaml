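# Activation of the wild-type receptor by the partial agonist P4S:
# tighter binding (per-site K_d 1.22e-5 M from the docking energetics)
# but a strongly reduced flipping equilibrium, which lowers maximal open
# probability and slows the onset relative to GABA.  Calibrated values.
name: glig_p4s
ligands: [P4S]
states:
  - {name: R,    class: closed}
  - {name: AR,   class: closed, bound: {P4S: 1}}
  - {name: A2R,  class: closed, bound: {P4S: 2}}
  - {name: A2F,  class: flipped, bound: {P4S: 2}}
  - {name: A2O,  class: open, conductance_weight: 1.0, bound: {P4S: 2}}
  - {name: A2D,  class: desensitized, bound: {P4S: 2}}
  - {name: A2Dp, class: desensitized, bound: {P4S: 2}}
transitions:
  - {from: R,    to: AR,   rate_name: kon1,  base_value: 2.0e+7, ligand: P4S, order: 1}
  - {from: AR,   to: R,    rate_name: koff1, base_value: 122.0}
  - {from: AR,   to: A2R,  rate_name: kon2,  base_value: 1.0e+7, ligand: P4S, order: 1}
  - {from: A2R,  to: AR,   rate_name: koff2, base_value: 244.0}
  - {from: A2R,  to: A2F,  rate_name: delta, base_value: 250.0}
  - {from: A2F,  to: A2R,  rate_name: gamma, base_value: 1500.0}
  - {from: A2F,  to: A2O,  rate_name: beta,  base_value: 8000.0}
  - {from: A2O,  to: A2F,  rate_name: alpha, base_value: 400.0}
  - {from: A2F,  to: A2D,  rate_name: d,     base_value: 20.0}
  - {from: A2D,  to: A2F,  rate_name: r,     base_value: 40.0}
  - {from: A2F,  to: A2Dp, rate_name: dp,    base_value: 12.0}
  - {from: A2Dp, to: A2F,  rate_name: rp,    base_value: 0.02}
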