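Subject,CA,AUC,SE,SP,Kappa,CT
S1,0.871,0.887,0.842,0.821,0.680,0.026
S2,0.842,0.882,0.914,0.757,0.675,0.030
S3,0.841,0.901,0.909,0.760,0.656,0.032
S4,0.889,0.887,0.884,0.826,0.685,0.027
S5,0.862,0.898,0.964,0.716,0.705,0.030
S6,0.917,0.978,0.878,0.918,0.784,0.035
S7,0.816,0.934,0.797,0.882,0.645,0.030
S8,0.861,0.941,0.833,0.880,0.717,0.034
S9,0.895,0.914,0.872,0.953,0.717,0.023
S10,0.864,0.941,0.809,0.934,0.717,0.029
S11,0.855,0.935,0.888,0.828,0.698,0.033
S12,0.851,0.950,0.851,0.930,0.712,0.040
S13,0.836,0.831,0.825,0.837,0.629,0.029
S14,0.880,0.866,0.877,0.885,0.763,0.029
S15,0.870,0.886,0.882,0.846,0.718,0.034
S16,0.857,0.868,0.821,0.832,0.720,0.019
S17,0.882,0.886,0.863,0.822,0.705,0.087
S18,0.872,0.90,0.905,0.805,0.705,0.037
S19,0.862,0.890,0.895,0.842,0.714,0.031
S20,0.859,0.879,0.830,0.930,0.704,0.031
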