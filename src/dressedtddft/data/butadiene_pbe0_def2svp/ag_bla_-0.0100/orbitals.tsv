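# index	energy_hartree	occupied
0	-1.0247897350138832e+01	1
1	-1.0247515243625321e+01	1
2	-1.0244141363412423e+01	1
3	-1.0244115036278201e+01	1
4	-8.2052756129295890e-01	1
5	-7.3324854575477993e-01	1
6	-6.2742185153559027e-01	1
7	-5.6577889477068333e-01	1
8	-4.7612192008584897e-01	1
9	-4.7423772002601211e-01	1
10	-4.0373400657243491e-01	1
11	-3.9553843296430435e-01	1
12	-3.6980780476885022e-01	1
13	-3.3862384432016979e-01	1
14	-2.3391690198709303e-01	1
15	-4.5938242921343256e-02	0
16	7.2651306830682702e-02	0
17	9.2899676746012086e-02	0
18	9.9829592387917415e-02	0
19	1.0549211481027067e-01	0
20	1.5273574546544624e-01	0
21	1.6726060196598430e-01	0
22	1.7875477763745265e-01	0
23	2.9103841489206572e-01	0
24	3.0814279842837738e-01	0
25	3.6069546742099662e-01	0
26	4.0204801450256000e-01	0
27	4.2344607894635744e-01	0
28	4.3040285228620984e-01	0
29	4.5768803088122501e-01	0
30	4.9690143361394451e-01	0
31	5.3247296296451752e-01	0
32	5.3991961931840726e-01	0
33	5.5011269931923568e-01	0
34	6.1493536334974752e-01	0
35	6.2248406061782713e-01	0
36	6.6189980030053186e-01	0
37	6.7411916918810999e-01	0
38	6.8388400311389430e-01	0
39	6.8927246689031918e-01	0
40	7.1208415211407006e-01	0
41	7.1303630447572830e-01	0
42	7.6700164784268066e-01	0
43	8.1816916813327689e-01	0
44	8.3264382523718472e-01	0
45	1.0091351672787447e+00	0
46	1.1294511893857730e+00	0
47	1.1654546248086368e+00	0
48	1.1901335572737066e+00	0
49	1.2091681424202472e+00	0
50	1.2316529042017246e+00	0
51	1.2706131689439726e+00	0
52	1.2958656661648364e+00	0
53	1.6019561983056538e+00	0
54	1.6041791379822752e+00	0
55	1.6420254188859131e+00	0
56	1.6471708972173360e+00	0
57	1.6642564848713577e+00	0
58	1.7249119508507458e+00	0
59	1.7573287779701683e+00	0
60	1.7752249200099897e+00	0
61	1.7782611136784152e+00	0
62	1.8076453833391977e+00	0
63	1.8830198582093640e+00	0
64	1.8917470313858689e+00	0
65	2.0155116543998135e+00	0
66	2.0346265452881376e+00	0
67	2.0798186291977370e+00	0
68	2.1061024364654783e+00	0
69	2.1214711254627407e+00	0
70	2.2562864700405747e+00	0
71	2.2870510385185225e+00	0
72	2.3084679837795909e+00	0
73	2.3084735722965051e+00	0
74	2.3840276749575584e+00	0
75	2.4911931565256245e+00	0
76	2.5309679263191875e+00	0
77	2.6170546529583048e+00	0
78	2.6882056384523301e+00	0
79	2.7046756692545855e+00	0
80	2.8321318651846505e+00	0
81	2.8355122142316977e+00	0
82	2.9790789563347069e+00	0
83	3.0132428724435543e+00	0
84	3.2916440127806577e+00	0
85	3.3622017491488565e+00	0
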