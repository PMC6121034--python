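# Flurazepam on spontaneous gating (wild type and mutants alike):
# opening rates up, closing rates down (longer open lifetimes with
# unchanged component fractions), resensitization of the unliganded
# desensitized state slowed.  Calibrated so the open/closing fold changes
# give an enhancement ratio near the measured ~2.3.
name: flu_spont
multipliers:
  beta0: 1.4
  beta0p: 1.4
  alpha0: 0.6
  alpha0p: 0.6
  r0: 0.4
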