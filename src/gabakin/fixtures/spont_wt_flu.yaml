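# Benzodiazepine modulation of wild-type spontaneous gating through an
# explicit modulator binding step R + M <-> RM.  The RM branch mirrors
# the unmodulated one with opening rates raised, closing rates lowered
# (longer open lifetimes, unchanged component fractions) and slower
# resensitization (modulator-dependent unliganded desensitization).
# konM/koffM follow the docking-derived flurazepam K_d of 4.93e-7 M at
# an assumed association rate of 1e7 M^-1 s^-1.  Calibrated values.
name: spont_wt_flu
ligands: [FLU]
states:
  - {name: R,    class: closed}
  - {name: O0,   class: open, conductance_weight: 1.0}
  - {name: O0p,  class: open, conductance_weight: 1.0}
  - {name: D0,   class: desensitized}
  - {name: RM,   class: closed, bound: {FLU: 1}}
  - {name: O0M,  class: open, conductance_weight: 1.0, bound: {FLU: 1}}
  - {name: O0Mp, class: open, conductance_weight: 1.0, bound: {FLU: 1}}
  - {name: D0M,  class: desensitized, bound: {FLU: 1}}
transitions:
  - {from: R,    to: O0,   rate_name: beta0,    base_value: 0.15}
  - {from: O0,   to: R,    rate_name: alpha0,   base_value: 1000.0}
  - {from: R,    to: O0p,  rate_name: beta0p,   base_value: 0.05}
  - {from: O0p,  to: R,    rate_name: alpha0p,  base_value: 200.0}
  - {from: R,    to: D0,   rate_name: d0,       base_value: 0.02}
  - {from: D0,   to: R,    rate_name: r0,       base_value: 0.2}
  - {from: R,    to: RM,   rate_name: konM,     base_value: 1.0e+7, ligand: FLU, order: 1}
  - {from: RM,   to: R,    rate_name: koffM,    base_value: 4.93}
  - {from: RM,   to: O0M,  rate_name: beta0M,   base_value: 0.21}
  - {from: O0M,  to: RM,   rate_name: alpha0M,  base_value: 600.0}
  - {from: RM,   to: O0Mp, rate_name: beta0Mp,  base_value: 0.07}
  - {from: O0Mp, to: RM,   rate_name: alpha0Mp, base_value: 120.0}
  - {from: RM,   to: D0M,  rate_name: d0M,      base_value: 0.02}
  - {from: D0M,  to: RM,   rate_name: r0M,      base_value: 0.08}
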