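name,length_mm,r_prox_mm,r_dist_mm,parent
RCA,109,1.51,1.48,
PDA,37,1.08,1.05,RCA
PLA,42,1.28,1.25,RCA
LMCA,32,1.88,1.79,
LAD,27,1.51,1.45,LMCA
LAD1,29,1.46,1.45,LAD
LAD2,69,1.38,1.06,LAD
LAD3,47,1.03,1.03,LAD2
LAD4,22,0.88,0.77,LAD2
DIAG,35,1.26,1.16,LMCA
LCX,21,1.48,1.47,LMCA
LCX1,16,1.32,1.29,LCX
LCX2,20,1.15,1.14,LCX1
LCX3,39,1.02,0.99,LCX2
MARG1,35,1.16,1.08,LCX
MARG2,30,0.98,0.96,LCX1
MARG3,37,1.02,1.00,LCX2
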