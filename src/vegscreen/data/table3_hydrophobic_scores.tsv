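number	sequence	score
1	QHKRKRKKSRIVL	30.3
2	KFRKRKKSRYIV	29.6
3	RKRKRKKSRYIVLS	28.8
4	IVFKRKRKKSRYLS	28.6
5	RKRKRKKSRKIVL	27.1
6	ILLVRKRKSRYKK	25.9
7	IVVRKRKSRYKH	25.4
8	IVVRKRKSRYRK	25.1
9	ILIVRKRKSRYKK	24.3
10	RKRKKSRKKHIL	24.1
reference	QKRKRKKSRYKS	23.7
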