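label,exp_cm1,calc_cm1,central_cm1
nu N2H35,3429,3520.79,3522.08
A: nu N1H,3349,3399.51,3437.05
nu C3=O1; nu C1=C2; beta N1H36,1688,1681.01,1664.17
nu C19=O2; beta N2H35,1668,1665.21,1662.83
"beta C8,13,16H9,14,19",1225,1225.5,1224.87
gamma N1H36; rho C15H17-18; delta_as C17H20-22,600,589.69,580.71
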