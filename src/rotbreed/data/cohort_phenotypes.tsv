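line	generation	sex	n	distance_mean	distance_sd	weight_mean	weight_sd
HCR	1	M	57	529.0	244.3	265.7	27.5
HCR	1	F	59	564.7	224.3	181.2	20.7
HCR	2	M	82	495.3	201.9	271.3	29.0
HCR	2	F	55	652.2	263.0	174.2	16.7
HCR	3	M	74	630.4	215.1	258.2	29.3
HCR	3	F	86	721.9	248.5	175.0	18.3
HCR	4	M	64	611.3	190.2	261.4	25.4
HCR	4	F	67	784.3	270.4	176.0	15.9
HCR	5	M	86	661.6	218.0	252.9	26.2
HCR	5	F	65	812.9	270.0	171.9	14.2
HCR	6	M	79	769.9	220.0	250.6	28.2
HCR	6	F	72	916.5	271.1	169.7	13.4
HCR	7	M	67	722.6	305.7	274.5	34.5
HCR	7	F	66	1116.2	420.6	174.4	17.9
HCR	8	M	96	543.7	313.0	263.9	35.4
HCR	8	F	89	795.8	420.8	174.1	15.7
HCR	9	M	118	600.0	272.8	257.4	29.3
HCR	9	F	116	889.2	381.9	172.3	17.0
HCR	10	M	140	799.0	261.6	257.7	32.6
HCR	10	F	98	1018.7	308.0	172.3	17.5
HCR	11	M	92	641.2	281.3	246.2	30.5
HCR	11	F	110	849.3	314.0	164.5	17.6
HCR	12	M	90	756.1	348.6	251.3	27.1
HCR	12	F	105	883.5	528.5	166.4	16.0
HCR	13	M	134	729.4	386.5	236.8	28.6
HCR	13	F	106	1024.2	651.6	158.8	19.1
HCR	14	M	112	1243.2	443.2	220.9	32.2
HCR	14	F	110	1703.6	602.7	154.9	16.2
HCR	15	M	122	1667.0	284.5	221.0	28.5
HCR	15	F	110	2023.8	424.5	152.1	15.1
HCR	16	M	106	1476.0	253.0	224.1	25.1
HCR	16	F	104	1475.0	236.9	158.0	17.2
HCR	17	M	146	1509.2	248.9	227.4	28.1
HCR	17	F	137	1595.6	264.7	157.4	17.8
HCR	18	M	149	1540.9	241.1	220.8	29.4
HCR	18	F	121	1658.5	256.4	156.5	17.5
HCR	19	M	126	1669.0	271.8	225.7	26.2
HCR	19	F	101	1787.4	263.0	160.1	15.4
HCR	20	M	135	1579.2	246.0	233.7	26.0
HCR	20	F	113	1661.3	233.2	156.6	15.0
HCR	21	M	115	1834.0	306.7	233.1	27.1
HCR	21	F	120	1934.1	291.0	160.2	14.6
HCR	22	M	140	1729.6	250.1	254.2	28.2
HCR	22	F	118	1902.0	279.5	167.8	16.0
HCR	23	M	122	1697.3	279.0	254.0	31.0
HCR	23	F	105	1867.1	290.6	173.5	16.8
HCR	24	M	110	1649.4	226.5	258.0	25.7
HCR	24	F	105	1834.2	264.9	173.8	18.5
HCR	25	M	124	1657.0	279.2	257.7	25.2
HCR	25	F	140	1913.6	258.5	172.5	15.2
HCR	26	M	168	1834.9	277.7	251.8	23.1
HCR	26	F	129	2053.1	357.0	163.5	12.1
HCR	27	M	145	2000.7	364.3	246.3	26.3
HCR	27	F	145	2295.2	392.6	163.8	14.8
HCR	28	M	112	1810.4	269.6	261.4	26.1
HCR	28	F	113	2108.6	297.5	169.1	14.0
LCR	1	M	61	372.3	157.1	280.6	29.0
LCR	1	F	64	421.1	176.7	178.3	17.2
LCR	2	M	58	268.7	116.4	296.7	31.2
LCR	2	F	68	333.8	123.6	187.5	12.9
LCR	3	M	86	309.5	119.5	287.3	34.2
LCR	3	F	81	325.3	96.2	186.3	17.2
LCR	4	M	72	302.6	89.2	297.6	27.8
LCR	4	F	66	366.9	106.0	194.7	16.0
LCR	5	M	58	252.4	73.0	299.9	38.4
LCR	5	F	92	326.1	104.9	194.7	19.1
LCR	6	M	74	281.7	73.0	293.8	31.1
LCR	6	F	81	333.9	108.8	195.7	19.2
LCR	7	M	78	263.0	139.2	312.7	29.5
LCR	7	F	63	356.3	150.3	203.8	17.6
LCR	8	M	70	157.7	93.4	313.6	24.2
LCR	8	F	73	259.6	104.8	209.4	23.9
LCR	9	M	95	171.7	65.3	320.8	39.3
LCR	9	F	103	260.3	81.8	205.5	20.6
LCR	10	M	76	167.3	94.4	321.9	25.6
LCR	10	F	74	245.0	88.5	213.8	18.8
LCR	11	M	124	156.5	60.9	318.6	38.7
LCR	11	F	121	217.7	72.4	207.2	20.8
LCR	12	M	98	182.8	90.6	321.4	36.5
LCR	12	F	104	267.9	102.8	211.9	21.5
LCR	13	M	109	150.4	51.6	336.2	31.5
LCR	13	F	107	215.2	69.5	216.9	16.7
LCR	14	M	98	205.8	57.8	304.2	32.6
LCR	14	F	111	266.4	78.4	207.2	20.9
LCR	15	M	111	240.3	75.9	318.3	40.4
LCR	15	F	120	318.7	102.7	214.4	21.4
LCR	16	M	63	303.2	69.3	314.3	29.9
LCR	16	F	78	370.0	107.3	208.0	28.0
LCR	17	M	127	318.3	75.6	316.8	35.5
LCR	17	F	127	367.4	87.2	203.8	19.4
LCR	18	M	127	282.6	58.2	323.5	32.8
LCR	18	F	119	374.6	69.3	202.7	18.0
LCR	19	M	123	281.3	78.4	327.7	32.1
LCR	19	F	115	363.9	92.0	213.6	19.1
LCR	20	M	113	272.3	64.0	326.7	29.2
LCR	20	F	120	330.7	87.3	208.0	19.4
LCR	21	M	112	291.3	90.4	336.3	30.7
LCR	21	F	114	356.3	83.8	203.9	19.2
LCR	22	M	99	328.9	63.6	335.1	30.8
LCR	22	F	105	389.2	65.8	202.3	16.6
LCR	23	M	103	248.3	38.0	339.8	32.3
LCR	23	F	88	322.5	45.7	210.8	17.6
LCR	24	M	88	238.1	30.1	354.9	24.3
LCR	24	F	84	308.9	47.0	214.8	19.2
LCR	25	M	115	228.0	65.2	340.6	33.2
LCR	25	F	110	346.5	73.3	205.3	17.7
LCR	26	M	117	201.7	45.1	327.0	50.3
LCR	26	F	123	305.3	49.4	206.2	19.4
LCR	27	M	135	217.8	49.6	331.6	31.7
LCR	27	F	119	309.3	64.1	206.4	14.4
LCR	28	M	115	191.8	42.9	328.2	31.5
LCR	28	F	111	278.3	45.8	208.6	16.7
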