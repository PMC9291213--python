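name,hb_role,charge_e,lj_epsilon_kcal,lj_sigma_ang,rmin_contrib_ang,comment
N1,donor,0.20,0.17,3.25,1.40,amide NH hydrogen-bond donor probe
O,acceptor,-0.20,0.21,2.96,1.40,carbonyl oxygen hydrogen-bond acceptor probe
C3,none,0.00,0.086,3.40,0.00,neutral methyl probe (no hydrogen bonding)
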