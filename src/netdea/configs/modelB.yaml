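# Model B: three subunits — one per evaluated dimension (efficiency,
# quality, access), linked by the production volumes.
#
# NOTE: documented reconstruction; see modelA.yaml.
name: modelB
divisions: [efficiency, quality, access]
inputs:
  efficiency: [E1, E2, E3, E4]
desirable_outputs:
  quality: [Q1, Q2, Q3]
  access: [A1]
undesirable_outputs:
  quality: [Q4, Q5, Q6, Q7]
  access: [A2, A3]
links:
  - [efficiency, quality, E7]
  - [efficiency, quality, E9]
  - [efficiency, access, E8]
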