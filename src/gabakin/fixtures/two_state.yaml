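# Minimal closed-open scheme used for closed-form checks.
name: two_state
ligands: []
states:
  - {name: C, class: closed}
  - {name: O, class: open, conductance_weight: 1.0}
transitions:
  - {from: C, to: O, rate_name: beta, base_value: 2.0}
  - {from: O, to: C, rate_name: alpha, base_value: 8.0}
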