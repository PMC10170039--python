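# Model D: model B with the staff headcount variables (E2, E3) replaced by
# personnel costs (E5) and outsourcing costs (E6) added to the first subunit.
#
# NOTE: documented reconstruction; see modelA.yaml.
name: modelD
divisions: [efficiency, quality, access]
inputs:
  efficiency: [E1, E4, E5, E6]
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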