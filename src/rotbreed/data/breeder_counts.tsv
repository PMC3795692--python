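generation	line	n_phenotyped	n_breeders	n_m	n_f
0	HCR		26	13	13
1	HCR	116	28	14	14
2	HCR	137	28	14	14
3	HCR	160	28	14	14
4	HCR	131	26	13	13
5	HCR	151	28	14	14
6	HCR	151	30	15	15
7	HCR	133	30	15	15
8	HCR	185	28	13	15
9	HCR	234	30	14	16
10	HCR	238	29	13	16
11	HCR	202	34	16	18
12	HCR	195	30	14	16
13	HCR	240	34	16	18
14	HCR	222	30	15	15
15	HCR	232	32	16	16
16	HCR	210	38	19	19
17	HCR	283	42	21	21
18	HCR	270	46	23	23
19	HCR	227	42	20	22
20	HCR	248	44	22	22
21	HCR	235	50	25	25
22	HCR	258	48	24	24
23	HCR	227	48	24	24
24	HCR	215	44	22	22
25	HCR	264	50	25	25
26	HCR	297	44	22	22
27	HCR	290
28	HCR	225
0	LCR		26	13	13
1	LCR	125	26	13	13
2	LCR	126	26	13	13
3	LCR	167	30	15	15
4	LCR	138	26	13	13
5	LCR	150	26	13	13
6	LCR	155	26	13	13
7	LCR	141	26	13	13
8	LCR	143	28	14	14
9	LCR	198	27	14	13
10	LCR	150	27	13	14
11	LCR	245	28	14	14
12	LCR	202	26	13	13
13	LCR	216	28	14	14
14	LCR	209	28	14	14
15	LCR	231	30	15	15
16	LCR	141	30	15	15
17	LCR	254	38	19	19
18	LCR	246	38	19	19
19	LCR	238	45	22	23
20	LCR	233	50	25	25
21	LCR	226	39	19	20
22	LCR	204	50	25	25
23	LCR	191	52	26	26
24	LCR	172	50	25	25
25	LCR	225	44	22	22
26	LCR	240	50	25	25
27	LCR	254
28	LCR	226
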