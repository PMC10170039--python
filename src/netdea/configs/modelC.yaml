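# Model C: model A with the staff headcount variables (E2, E3) replaced by
# personnel costs (E5) and outsourcing costs (E6) added to the first subunit.
#
# NOTE: documented reconstruction; see modelA.yaml.
name: modelC
divisions: [administration, inpatient, outpatient, surgical]
inputs:
  administration: [E1, E4, E5, E6]
desirable_outputs:
  inpatient: [Q1, Q2]
  outpatient: [Q3]
  surgical: [A1]
undesirable_outputs:
  inpatient: [Q4, Q5]
  outpatient: [A2]
  surgical: [Q6, Q7, A3]
links:
  - [administration, inpatient, E7]
  - [administration, outpatient, E8]
  - [administration, surgical, E9]
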