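# Spontaneous (agonist-free) gating of the wild-type alpha1-beta2-gamma2
# receptor: two open states of distinct lifetime and an unliganded
# desensitized state, all reached directly from rest (no pre-activation
# step, so openings are solitary and activity is burst-free).
# Rate values are package calibrations, not measured constants.
name: spont_wt
ligands: []
states:
  - {name: R,   class: closed}
  - {name: O0,  class: open, conductance_weight: 1.0}
  - {name: O0p, class: open, conductance_weight: 1.0}
  - {name: D0,  class: desensitized}
transitions:
  - {from: R,   to: O0,  rate_name: beta0,   base_value: 0.15}
  - {from: O0,  to: R,   rate_name: alpha0,  base_value: 1000.0}
  - {from: R,   to: O0p, rate_name: beta0p,  base_value: 0.05}
  - {from: O0p, to: R,   rate_name: alpha0p, base_value: 200.0}
  - {from: R,   to: D0,  rate_name: d0,      base_value: 0.02}
  - {from: D0,  to: R,   rate_name: r0,      base_value: 0.2}
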