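# index	energy_hartree	occupied
0	-1.0248437617070726e+01	1
1	-1.0248010910733070e+01	1
2	-1.0245485215456187e+01	1
3	-1.0245458881261687e+01	1
4	-8.2074434853384459e-01	1
5	-7.3102225959894018e-01	1
6	-6.2902229201652060e-01	1
7	-5.6586343576182041e-01	1
8	-4.7577382774717253e-01	1
9	-4.7352010118146604e-01	1
10	-4.0448500978760543e-01	1
11	-3.9459014311822355e-01	1
12	-3.7075971285626097e-01	1
13	-3.3867171655825357e-01	1
14	-2.3201003763024747e-01	1
15	-4.8627975881438711e-02	0
16	7.2377697767771462e-02	0
17	9.3080454808875918e-02	0
18	9.9837563692429382e-02	0
19	1.0525389707473261e-01	0
20	1.5239144145222164e-01	0
21	1.6660782466030788e-01	0
22	1.7914550348671709e-01	0
23	2.8860109456534466e-01	0
24	3.0630546893675759e-01	0
25	3.6006071108689836e-01	0
26	4.0145778237334628e-01	0
27	4.2567086759691064e-01	0
28	4.2990273169006765e-01	0
29	4.5765697633442382e-01	0
30	4.9725594535106632e-01	0
31	5.3035592045873059e-01	0
32	5.3979696345189454e-01	0
33	5.4925708060169376e-01	0
34	6.1562474542960288e-01	0
35	6.2103529568366778e-01	0
36	6.6168700576224371e-01	0
37	6.7414427446080749e-01	0
38	6.8349061811631462e-01	0
39	6.8898423982180534e-01	0
40	7.1152564870904034e-01	0
41	7.1309238878341707e-01	0
42	7.6021262178759252e-01	0
43	8.1958974527926332e-01	0
44	8.3197412382847968e-01	0
45	1.0079412724481092e+00	0
46	1.1260747143332015e+00	0
47	1.1654090053266823e+00	0
48	1.1911284535393289e+00	0
49	1.2089507569136531e+00	0
50	1.2296065855837819e+00	0
51	1.2706380608530399e+00	0
52	1.2955394643645697e+00	0
53	1.6018692772560090e+00	0
54	1.6043261202672854e+00	0
55	1.6405319602134742e+00	0
56	1.6443081093770782e+00	0
57	1.6634307591192228e+00	0
58	1.7252214950364153e+00	0
59	1.7553127354857945e+00	0
60	1.7702154072742391e+00	0
61	1.7832243127294842e+00	0
62	1.8086028490274828e+00	0
63	1.8827897641365257e+00	0
64	1.8871966696797531e+00	0
65	2.0126474275426540e+00	0
66	2.0356609149277962e+00	0
67	2.0815613493119414e+00	0
68	2.1094987677561701e+00	0
69	2.1182176659323155e+00	0
70	2.2539275315522347e+00	0
71	2.2833548260549148e+00	0
72	2.3015977404324146e+00	0
73	2.3075662878012926e+00	0
74	2.3805853073881162e+00	0
75	2.4860478722283279e+00	0
76	2.5311117238407537e+00	0
77	2.6209960958322260e+00	0
78	2.6830930237623765e+00	0
79	2.6986741122059268e+00	0
80	2.8326000218457623e+00	0
81	2.8356351833810027e+00	0
82	2.9770655045018724e+00	0
83	3.0099134444608655e+00	0
84	3.2841409448111927e+00	0
85	3.3608015665436684e+00	0
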