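number	sequence	score
1	QKRKRKKSRKKH	36.8
2	RKRKRKKSRKKH	36.8
3	KKRKRKKSRKRK	36.2
4	QKRKRKKSRYRK	35.6
5	QHRKRKKSRKRH	34.9
6	RKRKRKKSRYKK	34.7
7	QKRKRKKSRYKK	30.8
8	QKRKRKKSRRKK	29.5
9	QKRKRKKSRKK	28.8
10	QKRKRKKSRHKK	28.4
reference	QKRKRKKSRYKS	27.5
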