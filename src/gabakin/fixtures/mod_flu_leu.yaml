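# Flurazepam on GABA-evoked gating of the leucine mutant: flipping up,
# fast desensitization entry and exit up, slow-desensitization entry down.
name: flu_leu
multipliers:
  delta: 1.6
  d: 2.5
  r: 1.2
  dp: 0.5
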