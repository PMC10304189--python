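label,exp_cm1,calc_cm1,scaled_cm1
nu_as N3H3-4,3383,3484.85,3620.42
nu_s N3H3-4,3327.9,3331.83,3483.25
nu C1O1,1615,1671.64,1684.02
beta N3H3; nu C3N2,1498,1467.85,1516.19
"beta C5,7H5,8; omega C6H6-7; gamma C2H1",1184,1182.63,1151.56
omega C6H6-7; nu C6S1,752,757.16,750.6
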