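case,SingleModel,LibrarySampling,Bagging,Boosting
B1,5.184,1.103,1.073,1.065
B2,0.938,1.143,1.085,0.947
B3,1.042,0.794,0.968,0.941
B4,2.840,0.750,0.760,0.791
B5,0.842,0.858,0.859,0.698
K1,7.730,0.756,0.736,0.925
K2,328.138,0.878,1.429,1.642
K3,0.932,0.827,0.867,0.923
K4,0.777,0.800,0.772,0.705
K5,0.792,0.732,0.734,0.781
Z1,0.744,0.797,0.777,0.890
Z2,1.323,0.948,0.883,0.893
Z3,29.463,0.881,0.934,1.001
Z4,27.593,1.011,0.964,0.982
Z5,1.489,1.130,1.113,1.403
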