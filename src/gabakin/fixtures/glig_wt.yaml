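# GABA-evoked activation of the wild-type receptor: flipped (pre-activated)
# di-liganded scheme R <-> AR <-> A2R <-> A2F <-> A2O with fast (A2D) and
# slow (A2D') desensitized states branching from the flipped state.
# Binding uses explicit statistical factors for the two sites (2*kon into
# AR, 2*koff out of A2R); the per-site K_d of 1.54e-4 M follows the
# docking-derived GABA binding energy.  Gating values are package
# calibrations reproducing fast flipping and strong fast desensitization.
name: glig_wt
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
  - {from: A2R,  to: A2F,  rate_name: delta, base_value: 3000.0}
  - {from: A2F,  to: A2R,  rate_name: gamma, base_value: 2000.0}
  - {from: A2F,  to: A2O,  rate_name: beta,  base_value: 8000.0}
  - {from: A2O,  to: A2F,  rate_name: alpha, base_value: 400.0}
  - {from: A2F,  to: A2D,  rate_name: d,     base_value: 1200.0}
  - {from: A2D,  to: A2F,  rate_name: r,     base_value: 150.0}
  - {from: A2F,  to: A2Dp, rate_name: dp,    base_value: 100.0}
  - {from: A2Dp, to: A2F,  rate_name: rp,    base_value: 0.02}
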