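# Tautomer/stereo state space of the oxindole query scaffold:
# a 3-substituted indolin-2-one linked through a methylene to a pyrazolone.
#
# Two tautomer sites and one stereocenter:
#   * indole site  — lactam ("oxindole", C2=O, N1-H) vs imino-ol
#     ("hydroxy_indole", C2-OH, C2=N1).  Both keep C3 sp3, so the
#     stereocenter exists in every state.
#   * pyrazole site — five pyrazolone tautomers, labelled by the proton
#     positions on the two ring nitrogens and the oxygen
#     (N-NH=O, NH-NH=O, N-NH-OH, N-N-OH, NH-N-OH).
#   * one C3 stereocenter — two enantiomers ("@" assigned to enantiomer_1
#     by convention; the racemate makes the assignment arbitrary).
#
# 2 x 5 x 2 = 20 states.  Aliases give each combination its customary
# oxindole_1 .. oxindole_20 display id.
name: oxindole
template: "{indole}c2ccccc2[C{c3}H]1C{pyrazole}"
sites:
  - name: indole
    states:
      - {label: hydroxy_indole, fragment: "OC1=N"}
      - {label: oxindole, fragment: "O=C1N"}
  - name: pyrazole
    states:
      - {label: "NH-N-OH", fragment: "c1cc(O)[nH]n1"}
      - {label: "N-N-OH", fragment: "C1=NN=C(O)C1"}
      - {label: "N-NH-OH", fragment: "c1cc(O)n[nH]1"}
      - {label: "N-NH=O", fragment: "C1=NNC(=O)C1"}
      - {label: "NH-NH=O", fragment: "C1=CC(=O)NN1"}
stereocenters:
  - name: c3
    configs:
      - {label: enantiomer_1, tag: "@"}
      - {label: enantiomer_2, tag: "@@"}
aliases:
  "hydroxy_indole/NH-N-OH/enantiomer_1": oxindole_1
  "hydroxy_indole/N-N-OH/enantiomer_1": oxindole_2
  "hydroxy_indole/N-NH-OH/enantiomer_1": oxindole_3
  "hydroxy_indole/N-NH=O/enantiomer_1": oxindole_4
  "hydroxy_indole/NH-NH=O/enantiomer_1": oxindole_5
  "oxindole/NH-N-OH/enantiomer_1": oxindole_6
  "oxindole/N-N-OH/enantiomer_1": oxindole_7
  "oxindole/N-NH-OH/enantiomer_1": oxindole_8
  "oxindole/N-NH=O/enantiomer_1": oxindole_9
  "oxindole/NH-NH=O/enantiomer_1": oxindole_10
  "hydroxy_indole/NH-N-OH/enantiomer_2": oxindole_11
  "hydroxy_indole/N-N-OH/enantiomer_2": oxindole_12
  "hydroxy_indole/N-NH-OH/enantiomer_2": oxindole_13
  "hydroxy_indole/N-NH=O/enantiomer_2": oxindole_14
  "hydroxy_indole/NH-NH=O/enantiomer_2": oxindole_15
  "oxindole/NH-N-OH/enantiomer_2": oxindole_16
  "oxindole/N-N-OH/enantiomer_2": oxindole_17
  "oxindole/N-NH-OH/enantiomer_2": oxindole_18
  "oxindole/N-NH=O/enantiomer_2": oxindole_19
  "oxindole/NH-NH=O/enantiomer_2": oxindole_20
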