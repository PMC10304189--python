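label,exp_cm1,calc_cm1,scaled_cm1
nu O4H36,3428,3162.17,3566.16
nu N2H35,3307,3424.0,3478.29
nu C25O3; beta O4H36,1686,1666.48,1711.82
nu C17O1; beta N2H35; gamma C18H8,1635,1621.51,1665.09
"nu C7,18H; nu N2H",1300,1304.87,1273.02
"gamma N2H35; gamma C2,3,4,5H6,7,5,4; gamma C12-16H; nu C1N2",619,610.53,597.38
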