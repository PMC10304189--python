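label,exp_cm1,calc_cm1,central_cm1
nu_as N3H3-4,3383,3393.37,3484.85
nu_s N3H3-4,3327.9,3232.27,3331.83
nu C1O1,1651,1653.55,1671.64
beta N3H3; nu C3N2,1498,1498.19,1467.85
gamma C2H1; rho C8H9-10,1030,1033.46,1031.56
gamma N3H3; gamma C5H5,752,757.55,757.16
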