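label,exp_cm1,calc_cm1,scaled_cm1
nu O4H36,3428,3640.8,3566.16
nu N2H35,3307,3551.09,3478.29
"nu C12,16H",2804,2863.56,2804.86
nu C25O3; beta O4H36,1686,1747.65,1711.82
nu C17O1; beta N2H35; gamma C18H8,1635,1699.94,1665.09
"nu C7,18H; N2H",1300,1299.66,1273.02
gamma N2H35; omega C18H8-9; gamma C7-11H,474,475.74,465.99
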