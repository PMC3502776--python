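category	n_patients	mean_days_identification	min_days_identification	max_days_identification	mean_days_transplant	min_days_transplant	max_days_transplant	mean_donors_tested
high	66	54	20	208	101	24	428	4.92
intermediate	30	73	34	217	76	11	170	5.13
low	36	83	33	308	94	12	298	5.05
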