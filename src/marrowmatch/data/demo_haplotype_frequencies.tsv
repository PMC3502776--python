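A	B	C	DRB1	DQB1	frequency	population
A*01:01	B*08:01	C*07:01	DRB1*03:01	DQB1*02:01	0.070	EUR
A*03:01	B*07:02	C*07:02	DRB1*15:01	DQB1*06:02	0.060	EUR
A*02:01	B*44:02	C*05:01	DRB1*04:01	DQB1*03:02	0.045	EUR
A*02:01	B*07:02	C*07:02	DRB1*15:01	DQB1*06:02	0.040	EUR
A*29:02	B*44:03	C*16:01	DRB1*07:01	DQB1*02:02	0.035	EUR
A*02:01	B*15:01	C*03:04	DRB1*04:01	DQB1*03:02	0.030	EUR
A*23:01	B*44:03	C*04:01	DRB1*07:01	DQB1*02:02	0.028	EUR
A*02:01	B*51:01	C*15:02	DRB1*11:01	DQB1*03:01	0.028	EUR
A*24:02	B*07:02	C*07:02	DRB1*15:01	DQB1*06:02	0.025	EUR
A*01:01	B*57:01	C*06:02	DRB1*07:01	DQB1*03:03	0.025	EUR
A*02:01	B*40:01	C*03:04	DRB1*13:02	DQB1*06:04	0.022	EUR
A*11:01	B*35:01	C*04:01	DRB1*01:01	DQB1*05:01	0.022	EUR
A*02:01	B*18:01	C*07:01	DRB1*11:04	DQB1*03:01	0.020	EUR
A*25:01	B*18:01	C*12:03	DRB1*15:01	DQB1*06:02	0.020	EUR
A*26:01	B*38:01	C*12:03	DRB1*04:02	DQB1*03:02	0.018	EUR
A*02:01	B*13:02	C*06:02	DRB1*07:01	DQB1*02:02	0.018	EUR
A*03:01	B*35:01	C*04:01	DRB1*01:01	DQB1*05:01	0.018	EUR
A*31:01	B*40:02	C*02:02	DRB1*04:04	DQB1*03:02	0.016	EUR
A*02:01	B*27:05	C*02:02	DRB1*01:01	DQB1*05:01	0.016	EUR
A*30:01	B*13:02	C*06:02	DRB1*07:01	DQB1*02:02	0.016	EUR
A*32:01	B*14:02	C*08:02	DRB1*01:02	DQB1*05:01	0.015	EUR
A*68:01	B*44:02	C*07:04	DRB1*04:01	DQB1*03:01	0.015	EUR
A*02:05	B*50:01	C*06:02	DRB1*07:01	DQB1*02:02	0.006	EUR
A*33:01	B*14:02	C*08:02	DRB1*01:02	DQB1*05:01	0.005	EUR
A*02:01	B*35:02	C*04:01	DRB1*11:04	DQB1*03:01	0.005	EUR
A*24:02	B*35:03	C*04:01	DRB1*11:01	DQB1*03:01	0.005	EUR
A*02:01	B*35:08	C*04:01	DRB1*13:01	DQB1*06:03	0.004	EUR
A*30:02	B*53:01	C*04:01	DRB1*13:03	DQB1*03:01	0.004	EUR
A*68:02	B*53:01	C*04:01	DRB1*15:03	DQB1*06:02	0.003	EUR
A*02:01	B*44:05	C*02:02	DRB1*04:03	DQB1*03:05	0.003	EUR
A*02:17	B*41:01	C*17:01	DRB1*13:03	DQB1*03:01	0.002	EUR
A*03:01	B*47:01	C*06:02	DRB1*07:01	DQB1*03:03	0.003	EUR
A*11:01	B*55:01	C*03:03	DRB1*14:01	DQB1*05:03	0.004	EUR
A*24:02	B*18:01	C*02:02	DRB1*11:03	DQB1*03:01	0.002	EUR
A*01:01	B*52:01	C*12:02	DRB1*15:02	DQB1*06:01	0.004	EUR
A*26:01	B*51:01	C*16:02	DRB1*13:02	DQB1*06:09	0.002	EUR
A*02:01	B*57:01	C*06:02	DRB1*15:01	DQB1*06:03	0.002	EUR
A*25:01	B*44:02	C*05:01	DRB1*04:08	DQB1*03:01	0.002	EUR
A*33:03	B*58:01	C*03:02	DRB1*03:01	DQB1*02:01	0.003	EUR
A*02:151	B*07:02	C*07:02	DRB1*15:01	DQB1*06:02	0.001	EUR
A*03:20	B*51:08	C*16:02	DRB1*11:04	DQB1*03:01	0.001	EUR
A*24:02	B*07:20	C*07:02	DRB1*16:01	DQB1*05:02	0.001	EUR
A*31:01	B*39:01	C*12:03	DRB1*08:01	DQB1*04:02	0.004	EUR
A*68:01	B*40:01	C*03:04	DRB1*13:01	DQB1*06:03	0.002	EUR
A*02:01	B*15:17	C*07:01	DRB1*13:02	DQB1*06:04	0.002	EUR
A*29:01	B*07:05	C*15:05	DRB1*10:01	DQB1*05:01	0.002	EUR
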