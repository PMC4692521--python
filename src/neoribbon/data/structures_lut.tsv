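id	name	tissue	hemisphere
1	Frontal lobe left WM	WM	left
2	Frontal lobe right WM	WM	right
3	Parietal lobe left WM	WM	left
4	Parietal lobe right WM	WM	right
5	Occipital lobe left WM	WM	left
6	Occipital lobe right WM	WM	right
7	Anterior temporal lobe, medial part left WM	WM	left
8	Anterior temporal lobe, medial part right WM	WM	right
9	Anterior temporal lobe, lateral part left WM	WM	left
10	Anterior temporal lobe, lateral part right WM	WM	right
11	Gyri parahippocampalis et ambiens, anterior part left WM	WM	left
12	Gyri parahippocampalis et ambiens, anterior part right WM	WM	right
13	Gyri parahippocampalis et ambiens, posterior part left WM	WM	left
14	Gyri parahippocampalis et ambiens, posterior part right WM	WM	right
15	Superior temporal gyrus, middle part left WM	WM	left
16	Superior temporal gyrus, middle part right WM	WM	right
17	Superior temporal gyrus, posterior part left WM	WM	left
18	Superior temporal gyrus, posterior part right WM	WM	right
19	Medial and inferior temporal gyrus, anterior part left WM	WM	left
20	Medial and inferior temporal gyrus, anterior part right WM	WM	right
21	Medial and inferior temporal gyrus, posterior part left WM	WM	left
22	Medial and inferior temporal gyrus, posterior part right WM	WM	right
23	Fusiform gyrus, anterior part left WM	WM	left
24	Fusiform gyrus, anterior part right WM	WM	right
25	Fusiform gyrus, posterior part left WM	WM	left
26	Fusiform gyrus, posterior part right WM	WM	right
27	Insula left WM	WM	left
28	Insula right WM	WM	right
29	Cingulate gyrus, anterior part left WM	WM	left
30	Cingulate gyrus, anterior part right WM	WM	right
31	Cingulate gyrus, posterior part left WM	WM	left
32	Cingulate gyrus, posterior part right WM	WM	right
33	Frontal lobe left CGM	CGM	left
34	Frontal lobe right CGM	CGM	right
35	Parietal lobe left CGM	CGM	left
36	Parietal lobe right CGM	CGM	right
37	Occipital lobe left CGM	CGM	left
38	Occipital lobe right CGM	CGM	right
39	Anterior temporal lobe, medial part left CGM	CGM	left
40	Anterior temporal lobe, medial part right CGM	CGM	right
41	Anterior temporal lobe, lateral part left CGM	CGM	left
42	Anterior temporal lobe, lateral part right CGM	CGM	right
43	Gyri parahippocampalis et ambiens, anterior part left CGM	CGM	left
44	Gyri parahippocampalis et ambiens, anterior part right CGM	CGM	right
45	Gyri parahippocampalis et ambiens, posterior part left CGM	CGM	left
46	Gyri parahippocampalis et ambiens, posterior part right CGM	CGM	right
47	Superior temporal gyrus, middle part left CGM	CGM	left
48	Superior temporal gyrus, middle part right CGM	CGM	right
49	Superior temporal gyrus, posterior part left CGM	CGM	left
50	Superior temporal gyrus, posterior part right CGM	CGM	right
51	Medial and inferior temporal gyrus, anterior part left CGM	CGM	left
52	Medial and inferior temporal gyrus, anterior part right CGM	CGM	right
53	Medial and inferior temporal gyrus, posterior part left CGM	CGM	left
54	Medial and inferior temporal gyrus, posterior part right CGM	CGM	right
55	Fusiform gyrus, anterior part left CGM	CGM	left
56	Fusiform gyrus, anterior part right CGM	CGM	right
57	Fusiform gyrus, posterior part left CGM	CGM	left
58	Fusiform gyrus, posterior part right CGM	CGM	right
59	Insula left CGM	CGM	left
60	Insula right CGM	CGM	right
61	Cingulate gyrus, anterior part left CGM	CGM	left
62	Cingulate gyrus, anterior part right CGM	CGM	right
63	Cingulate gyrus, posterior part left CGM	CGM	left
64	Cingulate gyrus, posterior part right CGM	CGM	right
65	Hippocampus left	deepGM	left
66	Hippocampus right	deepGM	right
67	Amygdala left	deepGM	left
68	Amygdala right	deepGM	right
69	Cerebellum left	deepGM	left
70	Cerebellum right	deepGM	right
71	Brainstem	deepGM	midline
72	Caudate nucleus left	deepGM	left
73	Caudate nucleus right	deepGM	right
74	Thalamus left	deepGM	left
75	Thalamus right	deepGM	right
76	Sub-thalamic nucleus left	deepGM	left
77	Sub-thalamic nucleus right	deepGM	right
78	Lentiform nucleus left	deepGM	left
79	Lentiform nucleus right	deepGM	right
80	Corpus callosum	WM	midline
81	Lateral ventricle left	ventricle	left
82	Lateral ventricle right	ventricle	right
83	CSF	CSF	none
84	Intra-cranial background	background-intracranial	none
0	Extra-cranial background	background-extracranial	none
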