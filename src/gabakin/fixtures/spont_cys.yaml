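# Spontaneous gating of the alpha1-F64C (cysteine) binding-site mutant:
# opening rates raised (beta0, beta0p up, the slow-lifetime open state
# relatively more), closing and unliganded desensitization slightly
# lowered, mirroring the mutant's elevated resting activity with open
# lifetimes close to wild type.  Calibrated values.
name: spont_cys
ligands: []
states:
  - {name: R,   class: closed}
  - {name: O0,  class: open, conductance_weight: 1.0}
  - {name: O0p, class: open, conductance_weight: 1.0}
  - {name: D0,  class: desensitized}
transitions:
  - {from: R,   to: O0,  rate_name: beta0,   base_value: 0.45}
  - {from: O0,  to: R,   rate_name: alpha0,  base_value: 800.0}
  - {from: R,   to: O0p, rate_name: beta0p,  base_value: 0.35}
  - {from: O0p, to: R,   rate_name: alpha0p, base_value: 200.0}
  - {from: R,   to: D0,  rate_name: d0,      base_value: 0.01}
  - {from: D0,  to: R,   rate_name: r0,      base_value: 0.2}
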