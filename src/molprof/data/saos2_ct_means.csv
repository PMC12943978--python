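gene,mean_ct_control,mean_ct_treated
Tp53,32.49,32.73
RAD51,32.99,31.49
BRCA2,25.49,21.36
CASP2,30.01,27.71
MYC,30.70,30.14
MDM2,30.39,28.90
CDKN1A,32.75,28.37
ERCC1,30.29,28.59
ATR,29.95,28.30
PRKDC,31.17,30.43
GAPDH,24.93,20.17
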