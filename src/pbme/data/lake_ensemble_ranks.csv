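case,SingleModel,LibrarySampling,Bagging,Boosting
B1,4,3,2,1
B2,1,4,3,2
B3,4,1,3,2
B4,4,1,3,2
B5,2,3,4,1
K1,4,2,1,3
K2,4,1,2,3
K3,4,1,2,3
K4,3,4,2,1
K5,4,1,2,3
Z1,1,3,2,4
Z2,4,3,1,2
Z3,4,1,2,3
Z4,4,3,1,2
Z5,4,2,1,3
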