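# Prior dominance history for the five example males, as ordinal ranks
# (1 = most dominant), spread with the reciprocal-power index 0.3.
priorRankIndex: 0.3
priorRanks:
  DN: 1
  NK: 2
  ZF: 3
  MA: 4
  TK: 5
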