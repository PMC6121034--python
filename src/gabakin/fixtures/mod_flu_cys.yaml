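# Flurazepam on GABA-evoked gating of the cysteine mutant: flipping
# accelerated, slow-desensitization entry reduced.
name: flu_cys
multipliers:
  delta: 2.5
  dp: 0.5
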