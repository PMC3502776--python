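rare_allele	A	B	C	DRB1
A*02:151	A*02:151	B*07:02	C*07:02	DRB1*15:01
A*03:20	A*03:20	B*51:08	C*16:02	DRB1*11:04
A*03:50	A*03:50	B*35:01	C*04:01	DRB1*01:01
A*03:96	A*03:96	B*07:02	C*07:02	DRB1*15:01
A*03:102	A*03:102	B*18:01	C*02:02	DRB1*13:01
B*07:20	A*24:02	B*07:20	C*07:02	DRB1*16:01
B*27:70	A*02:01	B*27:70	C*02:02	DRB1*04:01
B*27:70	A*02:01	B*27:70	C*02:02	DRB1*04:04
B*51:43	A*02:01	B*51:43	C*14:02	DRB1*04:01
C*05:14	A*02:01	B*51:01	C*05:14	DRB1*04:04
C*15:13	A*02:01	B*51:01	C*15:13	DRB1*04:02
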