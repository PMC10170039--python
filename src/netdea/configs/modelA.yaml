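# Model A: four subunits — hospital administration (input-oriented) feeding
# three clinical services via patient-volume links.
#
# NOTE: this wiring is a documented reconstruction. The published diagram of
# the four hospital models is schematic and the exact variable-to-subunit
# assignment is not fully recoverable from it; adjust to taste and pass your
# own file to --model / read_model_spec.
name: modelA
divisions: [administration, inpatient, outpatient, surgical]
inputs:
  administration: [E1, E2, E3, E4]   # beds, doctor hours, nurse hours, operational costs
desirable_outputs:
  inpatient: [Q1, Q2]                # no unplanned readmission <30d, stay <30d
  outpatient: [Q3]                   # ambulatory surgeries on outpatient-eligible procedures
  surgical: [A1]                     # hip-fracture surgery within 48h
undesirable_outputs:
  inpatient: [Q4, Q5]                # pressure ulcers, CVC bloodstream infections
  outpatient: [A2]                   # first appointments beyond the legal time
  surgical: [Q6, Q7, A3]             # post-op sepsis, post-op PE/DVT, surgery waiting days
links:
  - [administration, inpatient, E7]  # inpatients treated
  - [administration, outpatient, E8] # outpatient appointments
  - [administration, surgical, E9]   # surgeries
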