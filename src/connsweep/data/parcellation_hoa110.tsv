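roi_index	region_name	abbreviation	hemisphere	lobe
1	Frontal pole	FP	L	frontal
2	Frontal pole	FP	R	frontal
3	Insular cortex	Insula	L	frontal
4	Insular cortex	Insula	R	frontal
5	Superior frontal gyrus	SFG	L	frontal
6	Superior frontal gyrus	SFG	R	frontal
7	Middle frontal gyrus	MFG	L	frontal
8	Middle frontal gyrus	MFG	R	frontal
9	Inferior frontal gyrus, pars triangularis	IFG_PTR	L	frontal
10	Inferior frontal gyrus, pars triangularis	IFG_PTR	R	frontal
11	Inferior frontal gyrus, pars opercularis	IFG_POP	L	frontal
12	Inferior frontal gyrus, pars opercularis	IFG_POP	R	frontal
13	Precentral gyrus	PrCG	L	frontal
14	Precentral gyrus	PrCG	R	frontal
15	Temporal pole	TP	L	temporal
16	Temporal pole	TP	R	temporal
17	Superior temporal gyrus, anterior division	aSTG	L	temporal
18	Superior temporal gyrus, anterior division	aSTG	R	temporal
19	Superior temporal gyrus, posterior division	pSTG	L	temporal
20	Superior temporal gyrus, posterior division	pSTG	R	temporal
21	Middle temporal gyrus, anterior division	aMTG	L	temporal
22	Middle temporal gyrus, anterior division	aMTG	R	temporal
23	Middle temporal gyrus, posterior division	pMTG	L	temporal
24	Middle temporal gyrus, posterior division	pMTG	R	temporal
25	Middle temporal gyrus, temporooccipital part	MTG_TOpart	L	temporal
26	Middle temporal gyrus, temporooccipital part	MTG_TOpart	R	temporal
27	Inferior temporal gyrus, anterior division	aITG	L	temporal
28	Inferior temporal gyrus, anterior division	aITG	R	temporal
29	Inferior temporal gyrus, posterior division	pITG	L	temporal
30	Inferior temporal gyrus, posterior division	pITG	R	temporal
31	Inferior temporal gyrus, temporooccipital part	ITG_TOpart	L	temporal
32	Inferior temporal gyrus, temporooccipital part	ITG_TOpart	R	temporal
33	Postcentral gyrus	PoCG	L	parietal
34	Postcentral gyrus	PoCG	R	parietal
35	Superior parietal lobule	SPL	L	parietal
36	Superior parietal lobule	SPL	R	parietal
37	Supramarginal gyrus, anterior division	aSMG	L	parietal
38	Supramarginal gyrus, anterior division	aSMG	R	parietal
39	Supramarginal gyrus, posterior division	pSMG	L	parietal
40	Supramarginal gyrus, posterior division	pSMG	R	parietal
41	Angular gyrus	AG	L	parietal
42	Angular gyrus	AG	R	parietal
43	Lateral occipital cortex, superior division	sLO	L	occipital
44	Lateral occipital cortex, superior division	sLO	R	occipital
45	Lateral occipital cortex, inferior division	iLO	L	occipital
46	Lateral occipital cortex, inferior division	iLO	R	occipital
47	Intracalcarine cortex	IntraCALC	L	occipital
48	Intracalcarine cortex	IntraCALC	R	occipital
49	Frontal medial cortex	FmC	L	frontal
50	Frontal medial cortex	FmC	R	frontal
51	Supplementary motor cortex	SMC	L	frontal
52	Supplementary motor cortex	SMC	R	frontal
53	Subcallosal cortex	SubCC	L	frontal
54	Subcallosal cortex	SubCC	R	frontal
55	Paracingulate gyrus	ParaCG	L	frontal
56	Paracingulate gyrus	ParaCG	R	frontal
57	Cingulate gyrus, anterior division	ACG	L	frontal
58	Cingulate gyrus, anterior division	ACG	R	frontal
59	Cingulate gyrus, posterior division	PCG	L	parietal
60	Cingulate gyrus, posterior division	PCG	R	parietal
61	Precuneous cortex	PrCN	L	parietal
62	Precuneous cortex	PrCN	R	parietal
63	Cuneal cortex	CN	L	occipital
64	Cuneal cortex	CN	R	occipital
65	Frontal orbital cortex	OFC	L	frontal
66	Frontal orbital cortex	OFC	R	frontal
67	Parahippocampal gyrus, anterior division	aPHG	L	temporal
68	Parahippocampal gyrus, anterior division	aPHG	R	temporal
69	Parahippocampal gyrus, posterior division	pPHG	L	temporal
70	Parahippocampal gyrus, posterior division	pPHG	R	temporal
71	Lingual gyrus	LG	L	occipital
72	Lingual gyrus	LG	R	occipital
73	Temporal fusiform cortex, anterior division	aTFC	L	temporal
74	Temporal fusiform cortex, anterior division	aTFC	R	temporal
75	Temporal fusiform cortex, posterior division	pTFC	L	temporal
76	Temporal fusiform cortex, posterior division	pTFC	R	temporal
77	Temporal occipital fusiform cortex	TOF	L	temporal
78	Temporal occipital fusiform cortex	TOF	R	temporal
79	Occipital fusiform gyrus	OF	L	occipital
80	Occipital fusiform gyrus	OF	R	occipital
81	Frontal operculum cortex	FO	L	frontal
82	Frontal operculum cortex	FO	R	frontal
83	Central opercular cortex	CO	L	frontal
84	Central opercular cortex	CO	R	frontal
85	Parietal operculum cortex	PO	L	parietal
86	Parietal operculum cortex	PO	R	parietal
87	Planum polare	PP	L	temporal
88	Planum polare	PP	R	temporal
89	Heschl's gyrus	HG	L	temporal
90	Heschl's gyrus	HG	R	temporal
91	Planum temporale	PT	L	temporal
92	Planum temporale	PT	R	temporal
93	Supracalcarine cortex	SupraCALC	L	occipital
94	Supracalcarine cortex	SupraCALC	R	occipital
95	Occipital pole	OP	L	occipital
96	Occipital pole	OP	R	occipital
97	Thalamus	Thalamus	L	subcortical
98	Thalamus	Thalamus	R	subcortical
99	Caudate	Caudate	L	subcortical
100	Caudate	Caudate	R	subcortical
101	Putamen	Putamen	L	subcortical
102	Putamen	Putamen	R	subcortical
103	Pallidum	Pallidum	L	subcortical
104	Pallidum	Pallidum	R	subcortical
105	Hippocampus	Hipp	L	subcortical
106	Hippocampus	Hipp	R	subcortical
107	Amygdala	AMY	L	subcortical
108	Amygdala	AMY	R	subcortical
109	Nucleus accumbens	NA	L	subcortical
110	Nucleus accumbens	NA	R	subcortical
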