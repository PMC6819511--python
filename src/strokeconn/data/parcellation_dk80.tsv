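label	name	hemisphere	tissue	surface_size	subnetwork	homotopic_label
1	bankssts_L	L	cortical	1000	ADN	41
2	caudalanteriorcingulate_L	L	cortical	700	ATT	42
3	caudalmiddlefrontal_L	L	cortical	2300	ATT	43
4	cuneus_L	L	cortical	1500	VRN	44
5	entorhinal_L	L	cortical	450	VRN	45
6	fusiform_L	L	cortical	3200	VRN	46
7	inferiorparietal_L	L	cortical	4800	DMN	47
8	inferiortemporal_L	L	cortical	3400	VRN	48
9	isthmuscingulate_L	L	cortical	950	DMN	49
10	lateraloccipital_L	L	cortical	4500	VRN	50
11	lateralorbitofrontal_L	L	cortical	2700	ATT	51
12	lingual_L	L	cortical	2900	VRN	52
13	medialorbitofrontal_L	L	cortical	1800	DMN	53
14	middletemporal_L	L	cortical	3300	DMN	54
15	parahippocampal_L	L	cortical	700	DMN	55
16	paracentral_L	L	cortical	1500	SMA	56
17	parsopercularis_L	L	cortical	1600	ATT	57
18	parsorbitalis_L	L	cortical	650	ATT	58
19	parstriangularis_L	L	cortical	1500	ATT	59
20	pericalcarine_L	L	cortical	1400	VRN	60
21	postcentral_L	L	cortical	4200	SMA	61
22	posteriorcingulate_L	L	cortical	1200	DMN	62
23	precentral_L	L	cortical	4800	SMA	63
24	precuneus_L	L	cortical	3800	DMN	64
25	rostralanteriorcingulate_L	L	cortical	800	DMN	65
26	rostralmiddlefrontal_L	L	cortical	5700	ATT	66
27	superiorfrontal_L	L	cortical	7000	SMA	67
28	superiorparietal_L	L	cortical	5300	ATT	68
29	superiortemporal_L	L	cortical	3600	ADN	69
30	supramarginal_L	L	cortical	3600	ATT	70
31	frontalpole_L	L	cortical	250	DMN	71
32	temporalpole_L	L	cortical	450	ADN	72
33	transversetemporal_L	L	cortical	400	ADN	73
34	insula_L	L	cortical	2200	ADN	74
35	thalamus_L	L	subcortical	1600	SN	75
36	caudate_L	L	subcortical	800	SN	76
37	putamen_L	L	subcortical	1100	SN	77
38	pallidum_L	L	subcortical	350	SN	78
39	hippocampus_L	L	subcortical	900	SN	79
40	amygdala_L	L	subcortical	350	SN	80
41	bankssts_R	R	cortical	1000	ADN	1
42	caudalanteriorcingulate_R	R	cortical	700	ATT	2
43	caudalmiddlefrontal_R	R	cortical	2300	ATT	3
44	cuneus_R	R	cortical	1500	VRN	4
45	entorhinal_R	R	cortical	450	VRN	5
46	fusiform_R	R	cortical	3200	VRN	6
47	inferiorparietal_R	R	cortical	4800	DMN	7
48	inferiortemporal_R	R	cortical	3400	VRN	8
49	isthmuscingulate_R	R	cortical	950	DMN	9
50	lateraloccipital_R	R	cortical	4500	VRN	10
51	lateralorbitofrontal_R	R	cortical	2700	ATT	11
52	lingual_R	R	cortical	2900	VRN	12
53	medialorbitofrontal_R	R	cortical	1800	DMN	13
54	middletemporal_R	R	cortical	3300	DMN	14
55	parahippocampal_R	R	cortical	700	DMN	15
56	paracentral_R	R	cortical	1500	SMA	16
57	parsopercularis_R	R	cortical	1600	ATT	17
58	parsorbitalis_R	R	cortical	650	ATT	18
59	parstriangularis_R	R	cortical	1500	ATT	19
60	pericalcarine_R	R	cortical	1400	VRN	20
61	postcentral_R	R	cortical	4200	SMA	21
62	posteriorcingulate_R	R	cortical	1200	DMN	22
63	precentral_R	R	cortical	4800	SMA	23
64	precuneus_R	R	cortical	3800	DMN	24
65	rostralanteriorcingulate_R	R	cortical	800	DMN	25
66	rostralmiddlefrontal_R	R	cortical	5700	ATT	26
67	superiorfrontal_R	R	cortical	7000	SMA	27
68	superiorparietal_R	R	cortical	5300	ATT	28
69	superiortemporal_R	R	cortical	3600	ADN	29
70	supramarginal_R	R	cortical	3600	ATT	30
71	frontalpole_R	R	cortical	250	DMN	31
72	temporalpole_R	R	cortical	450	ADN	32
73	transversetemporal_R	R	cortical	400	ADN	33
74	insula_R	R	cortical	2200	ADN	34
75	thalamus_R	R	subcortical	1600	SN	35
76	caudate_R	R	subcortical	800	SN	36
77	putamen_R	R	subcortical	1100	SN	37
78	pallidum_R	R	subcortical	350	SN	38
79	hippocampus_R	R	subcortical	900	SN	39
80	amygdala_R	R	subcortical	350	SN	40
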