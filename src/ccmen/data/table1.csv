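gene,role,code,nex,rnx,fc
PDGFRA,receptor,1,7.24,72.43,11.1
TGFB2R,receptor,2,5.21,52.14,3.58
EGFR,receptor,3,4,40,17.19
MET,receptor,4,2.7,27,1.95
IL4R,receptor,5,4.2,42,2.28
IL13R,receptor,6,7.34,73.43,4.48
TFR2,receptor,7,0.45,4.5,0.41
KDR,receptor,8,1.96,19.57,2.55
FGFR1,receptor,9,12.4,124,1.67
PLAUR,receptor,10,2.63,26.29,10.24
ITGA2B,receptor,11,1.69,16.86,0.71
PDGF,factor,1,12.77,127.71,1.95
TGFB2,factor,2,8.79,87.86,2.51
EGF,factor,3,0.27,2.71,1.36
HGF,factor,4,1.31,13.14,1.41
IL4,factor,5,0.2,2,1.1
IL13,factor,6,0.1,1,1.9
TF,factor,7,7.86,78.57,1.17
VEGF,factor,8,6.09,60.86,10.21
FGF2,factor,9,10.16,101.57,1.33
PLAU,factor,10,0.87,8.71,32.64
TNC,factor,11,1.79,17.86,78.92
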