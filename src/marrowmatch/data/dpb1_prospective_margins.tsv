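n_searches	donors_tested	n_dpb1_matched	n_hvg_only_included	min_donors_tested	max_donors_tested
33	90	14	1	1	5
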