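label,exp_cm1,calc_cm1,scaled_cm1
nu N2H35,3429,3522.08,3481.95
A: nu N1H,3349,3437.05,3479.12
nu C13H14,2914,2920.99,2894.87
nu C3=O1; nu C1=C2; beta N1H36,1688,1664.17,1678.21
nu C19=O2; beta N2H35,1668,1662.83,1676.69
"beta C8,13,16H9,14,19",1225,1224.87,1218.55
"beta N1H36; beta C6,10H6-7,10-11; delta_as C17,18H20-25",890,882.29,872.55
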