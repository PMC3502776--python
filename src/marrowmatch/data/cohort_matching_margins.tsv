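category	n_patients	donors_tested	n_10of10	n_9of10	n_8orless
high	103	331	102	1	0
intermediate	61	333	38	20	3
low	110	744	19	44	47
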