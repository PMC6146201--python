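Subject,CA,AUC,SE,SP,Kappa,CT
S1,0.816,0.868,0.934,0.736,0.715,102.647
S2,0.774,0.815,0.856,0.682,0.654,111.540
S3,0.819,0.860,0.860,0.781,0.666,107.877
S4,0.809,0.895,0.806,0.803,0.607,106.313
S5,0.840,0.833,0.853,0.835,0.698,101.316
S6,0.870,0.948,0.871,0.874,0.748,97.352
S7,0.848,0.858,0.812,0.814,0.708,92.272
S8,0.842,0.913,0.864,0.860,0.673,112.113
S9,0.866,0.849,0.867,0.875,0.725,86.093
S10,0.875,0.932,0.871,0.875,0.742,102.176
S11,0.858,0.911,0.798,0.879,0.707,109.576
S12,0.847,0.942,0.794,0.881,0.672,99.527
S13,0.791,0.840,0.788,0.809,0.645,109.510
S14,0.823,0.834,0.846,0.810,0.676,104.746
S15,0.848,0.877,0.897,0.827,0.693,87.300
S16,0.889,0.864,0.802,0.787,0.776,57.060
S17,0.855,0.831,0.919,0.817,0.704,103.555
S18,0.850,0.874,0.803,0.861,0.730,94.854
S19,0.867,0.880,0.850,0.825,0.732,95.346
S20,0.875,0.882,0.866,0.887,0.783,90.069
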