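label,exp_cm1,calc_cm1,central_cm1
nu O4H36,3428,3415.14,3162.17
nu N2H35,3307,3395.98,3424.0
nu C25O3; beta O4H36,1686,1689.41,1666.48
nu C17O1; beta N2H35; gamma C18H8,1635,1632.85,1621.51
"beta C7-12,14H; beta N2H35",1112,1125.59,1117.81
gamma N2H35; gamma O4H36; gamma C26H; ring puckering,763,758.78,743.32
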