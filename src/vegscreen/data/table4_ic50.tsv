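number	sequence	ic50_nmol_l	pm
reference	QKRKRKKSRYKS	464	12
15	QKRKRKKSRKKH	80	7
5	QFRKRKKSRWKS	92	9
17	RKRKRKKSRYIVLS	185	14
10	FFRKRKKSRYKS	188	25
11	QFRKRKKSRYKH	252	16
1	QFRKRKKSRYPK	273	19
9	KFRKRKKSRYIV	273	33
4	QKRKRKKSRYKY	280	13
18	RKRKRKKSRKKH	283	9
19	KKRKRKKSRKRK	315	11
14	QFRKRKKSRYKF	323	17
20	QKRKRKKSRYRK	405	20
16	QHKRKRKKSRIVL	424	37
8	QKRKRKKSRYPLS	542	16
6	QKRKRKKSRYKK	571	40
2	QKRKRKKSRYPK	602	19
12	IVFKRKRKKSRYLS	637	25
7	QFRKRKKSRYKS	665	38
13	QFRKRKKSRYLS	694	29
3	QFRKRKKSRYPS	4206	76
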