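number	sequence	energy_kcal_mol
1	QFRKRKKSRYPK	-6.2
2	QKRKRKKSRYPK	-6.0
3	QFRKRKKSRYPS	-5.9
4	QKRKRKKSRYKY	-5.8
5	QFRKRKKSRWKS	-5.6
6	QKRKRKKSRYKK	-5.5
7	QFRKRKKSRYKS	-5.4
8	KFRKRKKSRYKS	-5.4
9	FFRKRKKSRYKS	-5.3
10	QFRKRKKSRYKH	-5.3
11	HFRKRKKSRYKS	-5.3
12	QFRKRKKSRYLS	-5.3
13	QFRKRKKSRYKF	-5.2
14	QFRKRKKSRYKP	-5.2
15	QFRKRKKSRYKQ	-5.2
16	DKRKRKKSRYKS	-5.2
17	QKRKRKKSRYWS	-5.2
reference	QKRKRKKSRYKS	-5.0
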