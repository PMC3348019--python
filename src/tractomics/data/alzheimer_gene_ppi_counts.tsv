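index	gene	protein	n_ppi
1	A2M	HPRD_00072	28
2	ACTA1	HPRD_00030	91
3	ACTA2	HPRD_00031	15
4	APBA1	HPRD_03879	15
5	CTNNB1	HPRD_00286	135
6	DVL2	HPRD_03690	53
7	ERBB4	HPRD_02767	29
8	ERN1	HPRD_04943	12
9	FURIN	HPRD_00653	27
10	GSK3A	HPRD_06002	21
11	GSK3B	HPRD_05418	74
12	JUP	HPRD_01414	38
13	LRP1	HPRD_00138	55
14	LRP2	HPRD_02509	44
15	MAPK1	HPRD_01496	161
16	MAPK11	HPRD_04208	15
17	MAPK9	HPRD_04206	39
18	MAPKAPK5	HPRD_09467	19
19	MMP1	HPRD_00384	16
20	MMP14	HPRD_02856	20
21	MMP7	HPRD_01525	16
22	MMP9	HPRD_00387	31
23	NOTCH1	HPRD_01827	46
24	NOTCH2	HPRD_02606	16
25	PKN1	HPRD_03019	24
26	PLAU	HPRD_01883	16
27	PRKCB	HPRD_01499	68
28	PRKCD	HPRD_01501	103
29	PRKCG	HPRD_01502	48
30	PRKCQ	HPRD_02710	24
31	TRPC1	HPRD_11894	13
32	TRPC3	HPRD_15999	19
33	WNT3A	HPRD_05897	12
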