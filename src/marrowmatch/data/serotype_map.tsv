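allele	serotype
A*01:01	A1
A*02	A2
A*02:01	A2
A*02:05	A2
A*02:17	A2
A*02:151	A2
A*03	A3
A*03:01	A3
A*03:20	A3
A*03:50	A3
A*03:96	A3
A*03:102	A3
A*11:01	A11
A*23:01	A23
A*24:02	A24
A*25:01	A25
A*26:01	A26
A*29:01	A29
A*29:02	A29
A*30:01	A30
A*30:02	A30
A*31:01	A31
A*32:01	A32
A*33:01	A33
A*33:03	A33
A*68:01	A68
A*68:02	A68
B*07:02	B7
B*07:04	B7
B*07:05	B7
B*07:20	B7
B*08:01	B8
B*13:01	B13
B*13:02	B13
B*14:02	B65
B*15:01	B62
B*15:17	B63
B*18:01	B18
B*27:05	B27
B*27:70	B27
B*35	B35
B*35:01	B35
B*35:02	B35
B*35:03	B35
B*35:08	B35
B*38:01	B38
B*39:01	B39
B*40:01	B60
B*40:02	B61
B*41:01	B41
B*44	B44
B*44:02	B44
B*44:03	B44
B*44:05	B44
B*47:01	B47
B*50:01	B50
B*51:01	B51
B*51:08	B51
B*51:43	B51
B*52:01	B52
B*53:01	B53
B*55:01	B55
B*57:01	B57
B*58:01	B58
C*01:02	Cw1
C*02:02	Cw2
C*03:02	Cw3
C*03:03	Cw3
C*03:04	Cw3
C*04:01	Cw4
C*05:01	Cw5
C*05:14	Cw5
C*06:02	Cw6
C*07	Cw7
C*07:01	Cw7
C*07:02	Cw7
C*07:04	Cw7
C*08:02	Cw8
C*12:02	Cw12
C*12:03	Cw12
C*14:02	Cw14
C*15:02	Cw15
C*15:05	Cw15
C*15:13	Cw15
C*16:01	Cw16
C*16:02	Cw16
C*17:01	Cw17
DRB1*01:01	DR1
DRB1*01:02	DR1
DRB1*03:01	DR17
DRB1*04:01	DR4
DRB1*04:02	DR4
DRB1*04:03	DR4
DRB1*04:04	DR4
DRB1*04:08	DR4
DRB1*07:01	DR7
DRB1*08:01	DR8
DRB1*09:01	DR9
DRB1*10:01	DR10
DRB1*11:01	DR11
DRB1*11:03	DR11
DRB1*11:04	DR11
DRB1*12:01	DR12
DRB1*13:01	DR13
DRB1*13:02	DR13
DRB1*13:03	DR13
DRB1*14:01	DR14
DRB1*14:54	DR14
DRB1*15:01	DR15
DRB1*15:02	DR15
DRB1*15:03	DR15
DRB1*16:01	DR16
DQB1*02:01	DQ2
DQB1*02:02	DQ2
DQB1*03:01	DQ7
DQB1*03:02	DQ8
DQB1*03:05	DQ8
DQB1*03:03	DQ9
DQB1*04:02	DQ4
DQB1*05:01	DQ5
DQB1*05:02	DQ5
DQB1*05:03	DQ5
DQB1*06:01	DQ6
DQB1*06:02	DQ6
DQB1*06:03	DQ6
DQB1*06:04	DQ6
DQB1*06:09	DQ6
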