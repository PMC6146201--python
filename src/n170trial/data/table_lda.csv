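Subject,CA,AUC,SE,SP,Kappa,CT
S1,0.773,0.902,0.808,0.751,0.550,0.100
S2,0.753,0.874,0.759,0.746,0.503,0.104
S3,0.900,0.954,0.949,0.860,0.800,0.125
S4,0.800,0.864,0.741,0.859,0.594,0.137
S5,0.823,0.958,0.929,0.841,0.770,0.122
S6,0.876,0.951,0.852,0.816,0.736,0.057
S7,0.820,0.899,0.823,0.828,0.632,0.114
S8,0.840,0.935,0.805,0.887,0.678,0.107
S9,0.817,0.820,0.921,0.731,0.619,0.124
S10,0.880,0.941,0.853,0.903,0.750,0.105
S11,0.831,0.925,0.853,0.839,0.652,0.129
S12,0.823,0.894,0.853,0.749,0.632,0.291
S13,0.786,0.790,0.897,0.751,0.571,0.469
S14,0.825,0.865,0.786,0.760,0.628,0.359
S15,0.863,0.907,0.868,0.867,0.716,0.313
S16,0.846,0.874,0.837,0.788,0.695,0.339
S17,0.800,0.840,0.895,0.795,0.606,1.069
S18,0.863,0.934,0.833,0.869,0.714,0.372
S19,0.831,0.847,0.851,0.742,0.662,0.371
S20,0.843,0.854,0.823,0.867,0.735,0.360
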