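label,exp_cm1,calc_cm1,scaled_cm1
nu N2H35,3429,3517.12,3481.95
A: nu N1H,3349,3514.26,3479.12
nu C13H14,2914,2924.11,2894.87
nu C3=O1; nu C1=C2; beta N1H36,1688,1695.16,1678.21
nu C19=O2; beta N2H35,1668,1693.63,1676.69
"beta C8,16H9,19",1277,1268.44,1255.76
rho C14-15H15-18; gamma N2C19,766,766.83,759.16
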