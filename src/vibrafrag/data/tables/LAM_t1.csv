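label,exp_cm1,calc_cm1,scaled_cm1
nu_as N3H3-4,3383,3656.99,3620.42
nu_s N3H3-4,3328,3518.43,3483.25
nu C1O1,1651,1701.03,1684.02
nu C3N2; beta N3H3,1498,1531.51,1516.19
gamma C2H1; rho C8H9-10,1030,1041.08,1033.67
"rho N3H3-4; beta C5H5; gamma C4,6H2,6; gamma C8H9-10; ring puckering",538,533.74,528.4
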