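# Synthetic drug-like decoy vocabulary (combinatorially generated,
# not extracted from any database); SMILES <space> id.
CN(C)Cc1ccccc1 decoy_001
CNC(=O)c1ccccc1 decoy_002
O=C(O)Cc1ccccc1 decoy_003
Cc1cccc2ccccc12 decoy_004
CCc1cccc2ccccc12 decoy_005
OCCc1cccc2ccccc12 decoy_006
NCCc1cccc2ccccc12 decoy_007
CC(C)c1cccc2ccccc12 decoy_008
COCc1cccc2ccccc12 decoy_009
CN(C)Cc1cccc2ccccc12 decoy_010
FCc1cccc2ccccc12 decoy_011
ClCc1cccc2ccccc12 decoy_012
CNC(=O)c1cccc2ccccc12 decoy_013
O=C(O)Cc1cccc2ccccc12 decoy_014
c1ccc(CCc2cccc3ccccc23)cc1 decoy_015
c1ccc(-c2cccc3ccccc23)cc1 decoy_016
CN(C)Cc1cccnc1 decoy_017
CNC(=O)c1cccnc1 decoy_018
O=C(O)Cc1cccnc1 decoy_019
c1ccc(CCc2cccnc2)cc1 decoy_020
c1ccc(-c2cccnc2)cc1 decoy_021
Cc1ccccc1-c1ccccc1 decoy_022
CCc1ccccc1-c1ccccc1 decoy_023
OCCc1ccccc1-c1ccccc1 decoy_024
NCCc1ccccc1-c1ccccc1 decoy_025
CC(C)c1ccccc1-c1ccccc1 decoy_026
COCc1ccccc1-c1ccccc1 decoy_027
CN(C)Cc1ccccc1-c1ccccc1 decoy_028
FCc1ccccc1-c1ccccc1 decoy_029
ClCc1ccccc1-c1ccccc1 decoy_030
CNC(=O)c1ccccc1-c1ccccc1 decoy_031
O=C(O)Cc1ccccc1-c1ccccc1 decoy_032
Cc1cccc2[nH]ccc12 decoy_033
CCc1cccc2[nH]ccc12 decoy_034
OCCc1cccc2[nH]ccc12 decoy_035
NCCc1cccc2[nH]ccc12 decoy_036
CC(C)c1cccc2[nH]ccc12 decoy_037
COCc1cccc2[nH]ccc12 decoy_038
CN(C)Cc1cccc2[nH]ccc12 decoy_039
FCc1cccc2[nH]ccc12 decoy_040
ClCc1cccc2[nH]ccc12 decoy_041
CNC(=O)c1cccc2[nH]ccc12 decoy_042
O=C(O)Cc1cccc2[nH]ccc12 decoy_043
c1ccc(CCc2cccc3[nH]ccc23)cc1 decoy_044
c1ccc(-c2cccc3[nH]ccc23)cc1 decoy_045
Cc1cccc2ncccc12 decoy_046
CCc1cccc2ncccc12 decoy_047
OCCc1cccc2ncccc12 decoy_048
NCCc1cccc2ncccc12 decoy_049
CC(C)c1cccc2ncccc12 decoy_050
COCc1cccc2ncccc12 decoy_051
CN(C)Cc1cccc2ncccc12 decoy_052
FCc1cccc2ncccc12 decoy_053
ClCc1cccc2ncccc12 decoy_054
CNC(=O)c1cccc2ncccc12 decoy_055
O=C(O)Cc1cccc2ncccc12 decoy_056
c1ccc(CCc2cccc3ncccc23)cc1 decoy_057
c1ccc(-c2cccc3ncccc23)cc1 decoy_058
CCN1CCN(c2ccccc2)CC1 decoy_059
CCCN1CCN(c2ccccc2)CC1 decoy_060
OCCCN1CCN(c2ccccc2)CC1 decoy_061
NCCCN1CCN(c2ccccc2)CC1 decoy_062
CC(C)CN1CCN(c2ccccc2)CC1 decoy_063
COCCN1CCN(c2ccccc2)CC1 decoy_064
CN(C)CCN1CCN(c2ccccc2)CC1 decoy_065
FCCN1CCN(c2ccccc2)CC1 decoy_066
ClCCN1CCN(c2ccccc2)CC1 decoy_067
CNC(=O)CN1CCN(c2ccccc2)CC1 decoy_068
O=C(O)CCN1CCN(c2ccccc2)CC1 decoy_069
Cc1ccccc1C(=O)Nc1ccccc1 decoy_070
CCc1ccccc1C(=O)Nc1ccccc1 decoy_071
O=C(Nc1ccccc1)c1ccccc1CCO decoy_072
NCCc1ccccc1C(=O)Nc1ccccc1 decoy_073
CC(C)c1ccccc1C(=O)Nc1ccccc1 decoy_074
COCc1ccccc1C(=O)Nc1ccccc1 decoy_075
CN(C)Cc1ccccc1C(=O)Nc1ccccc1 decoy_076
O=C(Nc1ccccc1)c1ccccc1CF decoy_077
O=C(Nc1ccccc1)c1ccccc1CCl decoy_078
CNC(=O)c1ccccc1C(=O)Nc1ccccc1 decoy_079
O=C(O)Cc1ccccc1C(=O)Nc1ccccc1 decoy_080
O=C(Nc1ccccc1)c1ccccc1CCc1ccccc1 decoy_081
O=C(Nc1ccccc1)c1ccccc1-c1ccccc1 decoy_082
CNS(=O)(=O)c1ccccc1 decoy_083
CCNS(=O)(=O)c1ccccc1 decoy_084
O=S(=O)(NCCO)c1ccccc1 decoy_085
NCCNS(=O)(=O)c1ccccc1 decoy_086
CC(C)NS(=O)(=O)c1ccccc1 decoy_087
COCNS(=O)(=O)c1ccccc1 decoy_088
CN(C)CNS(=O)(=O)c1ccccc1 decoy_089
O=S(=O)(NCF)c1ccccc1 decoy_090
O=S(=O)(NCCl)c1ccccc1 decoy_091
CNC(=O)NS(=O)(=O)c1ccccc1 decoy_092
O=C(O)CNS(=O)(=O)c1ccccc1 decoy_093
CNCC(O)COc1ccccc1 decoy_094
CCNCC(O)COc1ccccc1 decoy_095
OCCNCC(O)COc1ccccc1 decoy_096
NCCNCC(O)COc1ccccc1 decoy_097
CC(C)NCC(O)COc1ccccc1 decoy_098
COCNCC(O)COc1ccccc1 decoy_099
CN(C)CNCC(O)COc1ccccc1 decoy_100
OC(CNCF)COc1ccccc1 decoy_101
OC(CNCCl)COc1ccccc1 decoy_102
CNC(=O)NCC(O)COc1ccccc1 decoy_103
O=C(O)CNCC(O)COc1ccccc1 decoy_104
CN(C)CN1CCCC1=O decoy_105
CNC(=O)N1CCCC1=O decoy_106
O=C(O)CN1CCCC1=O decoy_107
O=C1CCCN1CCc1ccccc1 decoy_108
O=C1CCCN1c1ccccc1 decoy_109
COC(=O)c1ccccc1 decoy_110
CCOC(=O)c1ccccc1 decoy_111
O=C(OCCO)c1ccccc1 decoy_112
NCCOC(=O)c1ccccc1 decoy_113
CC(C)OC(=O)c1ccccc1 decoy_114
COCOC(=O)c1ccccc1 decoy_115
CN(C)COC(=O)c1ccccc1 decoy_116
O=C(OCF)c1ccccc1 decoy_117
O=C(OCCl)c1ccccc1 decoy_118
CNC(=O)OC(=O)c1ccccc1 decoy_119
O=C(O)COC(=O)c1ccccc1 decoy_120
CNC(=O)/C=C/c1ccccc1 decoy_121
CCNC(=O)/C=C/c1ccccc1 decoy_122
O=C(/C=C/c1ccccc1)NCCO decoy_123
NCCNC(=O)/C=C/c1ccccc1 decoy_124
CC(C)NC(=O)/C=C/c1ccccc1 decoy_125
COCNC(=O)/C=C/c1ccccc1 decoy_126
CN(C)CNC(=O)/C=C/c1ccccc1 decoy_127
O=C(/C=C/c1ccccc1)NCF decoy_128
O=C(/C=C/c1ccccc1)NCCl decoy_129
CNC(=O)NC(=O)/C=C/c1ccccc1 decoy_130
O=C(O)CNC(=O)/C=C/c1ccccc1 decoy_131
CN(C)CC1CCCCC1 decoy_132
CNC(=O)C1CCCCC1 decoy_133
O=C(O)CC1CCCCC1 decoy_134
c1ccc(CCC2CCCCC2)cc1 decoy_135
c1ccc(C2CCCCC2)cc1 decoy_136
c1ccc(CCc2ccno2)cc1 decoy_137
c1ccc(-c2ccno2)cc1 decoy_138
Cn1c(=O)[nH]c2ccccc21 decoy_139
CCn1c(=O)[nH]c2ccccc21 decoy_140
O=c1[nH]c2ccccc2n1CCO decoy_141
NCCn1c(=O)[nH]c2ccccc21 decoy_142
CC(C)n1c(=O)[nH]c2ccccc21 decoy_143
COCn1c(=O)[nH]c2ccccc21 decoy_144
CN(C)Cn1c(=O)[nH]c2ccccc21 decoy_145
O=c1[nH]c2ccccc2n1CF decoy_146
O=c1[nH]c2ccccc2n1CCl decoy_147
CNC(=O)n1c(=O)[nH]c2ccccc21 decoy_148
O=C(O)Cn1c(=O)[nH]c2ccccc21 decoy_149
O=c1[nH]c2ccccc2n1CCc1ccccc1 decoy_150
O=c1[nH]c2ccccc2n1-c1ccccc1 decoy_151
Cc1cccc(CN2CCOCC2)c1 decoy_152
CCc1cccc(CN2CCOCC2)c1 decoy_153
OCCc1cccc(CN2CCOCC2)c1 decoy_154
NCCc1cccc(CN2CCOCC2)c1 decoy_155
CC(C)c1cccc(CN2CCOCC2)c1 decoy_156
COCc1cccc(CN2CCOCC2)c1 decoy_157
CN(C)Cc1cccc(CN2CCOCC2)c1 decoy_158
FCc1cccc(CN2CCOCC2)c1 decoy_159
ClCc1cccc(CN2CCOCC2)c1 decoy_160
CNC(=O)c1cccc(CN2CCOCC2)c1 decoy_161
O=C(O)Cc1cccc(CN2CCOCC2)c1 decoy_162
c1ccc(CCc2cccc(CN3CCOCC3)c2)cc1 decoy_163
c1ccc(-c2cccc(CN3CCOCC3)c2)cc1 decoy_164
Cc1cccc(-c2ncco2)c1 decoy_165
CCc1cccc(-c2ncco2)c1 decoy_166
OCCc1cccc(-c2ncco2)c1 decoy_167
NCCc1cccc(-c2ncco2)c1 decoy_168
CC(C)c1cccc(-c2ncco2)c1 decoy_169
COCc1cccc(-c2ncco2)c1 decoy_170
CN(C)Cc1cccc(-c2ncco2)c1 decoy_171
FCc1cccc(-c2ncco2)c1 decoy_172
ClCc1cccc(-c2ncco2)c1 decoy_173
CNC(=O)c1cccc(-c2ncco2)c1 decoy_174
O=C(O)Cc1cccc(-c2ncco2)c1 decoy_175
c1ccc(CCc2cccc(-c3ncco3)c2)cc1 decoy_176
c1ccc(-c2cccc(-c3ncco3)c2)cc1 decoy_177
CN1CCCc2ccccc21 decoy_178
CCN1CCCc2ccccc21 decoy_179
OCCN1CCCc2ccccc21 decoy_180
NCCN1CCCc2ccccc21 decoy_181
CC(C)N1CCCc2ccccc21 decoy_182
COCN1CCCc2ccccc21 decoy_183
CN(C)CN1CCCc2ccccc21 decoy_184
FCN1CCCc2ccccc21 decoy_185
ClCN1CCCc2ccccc21 decoy_186
CNC(=O)N1CCCc2ccccc21 decoy_187
O=C(O)CN1CCCc2ccccc21 decoy_188
c1ccc(CCN2CCCc3ccccc32)cc1 decoy_189
c1ccc(N2CCCc3ccccc32)cc1 decoy_190
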