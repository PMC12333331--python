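# index	energy_hartree	occupied
0	-1.0242816411460986e+01	1
1	-1.0242669583151546e+01	1
2	-1.0234096232213469e+01	1
3	-1.0234069338393189e+01	1
4	-8.2144926032728516e-01	1
5	-7.4982655504610796e-01	1
6	-6.1505579595473192e-01	1
7	-5.6483363768206885e-01	1
8	-4.7972577581584375e-01	1
9	-4.7861496406248327e-01	1
10	-4.0494938760716664e-01	1
11	-3.9829582935733204e-01	1
12	-3.5849924615613793e-01	1
13	-3.3979037834555176e-01	1
14	-2.4808799130273274e-01	1
15	-2.6159716916952909e-02	0
16	7.6669374296729528e-02	0
17	9.1279920246718535e-02	0
18	9.9691589805686792e-02	0
19	1.0685091436425334e-01	0
20	1.5454309090385740e-01	0
21	1.7189082828324651e-01	0
22	1.7409535535103154e-01	0
23	2.9601322537533303e-01	0
24	3.2130345435216695e-01	0
25	3.7321257046425121e-01	0
26	4.0190800074312028e-01	0
27	4.0822320459909928e-01	0
28	4.3897687109461853e-01	0
29	4.5905906422202086e-01	0
30	4.9186598559500222e-01	0
31	5.4005618474055495e-01	0
32	5.4612993886356909e-01	0
33	5.5678014110543039e-01	0
34	6.1162707336580924e-01	0
35	6.3323955692204414e-01	0
36	6.6216022834343391e-01	0
37	6.7374823044564580e-01	0
38	6.8526259805176160e-01	0
39	6.8710399830743607e-01	0
40	7.1220335882200769e-01	0
41	7.2040706112420771e-01	0
42	7.9941043066899087e-01	0
43	8.2754894864159811e-01	0
44	8.6361547744774325e-01	0
45	1.0121301729068899e+00	0
46	1.1551587412585893e+00	0
47	1.1744587407524172e+00	0
48	1.1830268337744698e+00	0
49	1.2102128330084014e+00	0
50	1.2492677731253250e+00	0
51	1.2729952892607366e+00	0
52	1.3055910374570647e+00	0
53	1.5955859185019301e+00	0
54	1.6024353103384192e+00	0
55	1.6303015284696214e+00	0
56	1.6595266745041084e+00	0
57	1.6673265820661920e+00	0
58	1.7208339891365658e+00	0
59	1.7699068942516141e+00	0
60	1.7727349987592262e+00	0
61	1.8029527006826274e+00	0
62	1.8188663302714276e+00	0
63	1.8871566447732788e+00	0
64	1.9271394599648635e+00	0
65	2.0276203994166822e+00	0
66	2.0386543737188210e+00	0
67	2.0663136339207462e+00	0
68	2.0787658211758004e+00	0
69	2.1432954188036630e+00	0
70	2.2763571355969483e+00	0
71	2.3165301303059915e+00	0
72	2.3176495571616913e+00	0
73	2.3591115245781715e+00	0
74	2.4093321433197055e+00	0
75	2.5315247327108130e+00	0
76	2.5388444612925620e+00	0
77	2.5949196145812161e+00	0
78	2.7267535808495631e+00	0
79	2.7603361299318476e+00	0
80	2.8352889967879520e+00	0
81	2.8404682087497766e+00	0
82	2.9958249001392292e+00	0
83	3.0387093256693589e+00	0
84	3.3482430597474027e+00	0
85	3.3771282289515492e+00	0
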