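# Het codes of common crystallization adjuvants, solvents, buffer
# components and ions removed from PDB-dialect ligand corpora.
HOH
DOD
SO4
PO4
GOL
EDO
PEG
PGE
PG4
DMS
ACT
FMT
NO3
ACE
ACY
BME
MPD
TRS
EPE
MES
IMD
CIT
TLA
NH4
CL
BR
IOD
F
NA
K
LI
CS
MG
CA
ZN
MN
FE
FE2
NI
CO
CU
CD
HG
SR
BA
AL
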