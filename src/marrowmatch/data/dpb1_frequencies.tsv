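allele	frequency
DPB1*04:01	0.390
DPB1*02:01	0.210
DPB1*04:02	0.130
DPB1*03:01	0.100
DPB1*01:01	0.060
DPB1*05:01	0.030
DPB1*06:01	0.020
DPB1*11:01	0.015
DPB1*13:01	0.012
DPB1*14:01	0.010
DPB1*09:01	0.008
DPB1*10:01	0.006
DPB1*17:01	0.005
DPB1*19:01	0.004
DPB1*15:01	0.004
DPB1*16:01	0.003
DPB1*20:01	0.002
DPB1*23:01	0.001
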