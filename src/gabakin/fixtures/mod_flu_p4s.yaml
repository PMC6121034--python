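# Flurazepam on P4S-evoked gating of the wild type: as for the leucine
# mutant but with the fast resensitization rate untouched.
name: flu_p4s
multipliers:
  delta: 2.5
  d: 15.0
  dp: 0.5
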