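# index	energy_hartree	occupied
0	-1.0247608962228847e+01	1
1	-1.0247247985601961e+01	1
2	-1.0243460367659408e+01	1
3	-1.0243434011984018e+01	1
4	-8.2045215905818636e-01	1
5	-7.3437585118163384e-01	1
6	-6.2660462328455435e-01	1
7	-5.6573153081875494e-01	1
8	-4.7629629217998964e-01	1
9	-4.7460209022478855e-01	1
10	-4.0335581298956558e-01	1
11	-3.9607739392676999e-01	1
12	-3.6924214900204239e-01	1
13	-3.3862007382473058e-01	1
14	-2.3488142045695609e-01	1
15	-4.4580212606872290e-02	0
16	7.2817277393913776e-02	0
17	9.2805021726753076e-02	0
18	9.9824701176126782e-02	0
19	1.0560635960644711e-01	0
20	1.5289804707149476e-01	0
21	1.6758872574886557e-01	0
22	1.7853587174525870e-01	0
23	2.9207861619102704e-01	0
24	3.0906667562771190e-01	0
25	3.6115299319771099e-01	0
26	4.0227446610551792e-01	0
27	4.2231665337143809e-01	0
28	4.3073107804652128e-01	0
29	4.5772439896620443e-01	0
30	4.9668924206168674e-01	0
31	5.3351921004957603e-01	0
32	5.3997361227368479e-01	0
33	5.5055158290039463e-01	0
34	6.1460920989481604e-01	0
35	6.2321674755020484e-01	0
36	6.6199288151121727e-01	0
37	6.7410101939879630e-01	0
38	6.8405293762128017e-01	0
39	6.8934261930611984e-01	0
40	7.1243764824983624e-01	0
41	7.1298379591209005e-01	0
42	7.7059541902679796e-01	0
43	8.1690872415148885e-01	0
44	8.3376748052690230e-01	0
45	1.0096562814088548e+00	0
46	1.1311667063804960e+00	0
47	1.1655988510983302e+00	0
48	1.1896314953181952e+00	0
49	1.2092699839546401e+00	0
50	1.2327211508302287e+00	0
51	1.2706360840525857e+00	0
52	1.2961313102157228e+00	0
53	1.6019110601218722e+00	0
54	1.6040949138024245e+00	0
55	1.6424924155170804e+00	0
56	1.6484792496083738e+00	0
57	1.6646325462129363e+00	0
58	1.7247379578421429e+00	0
59	1.7583553136574419e+00	0
60	1.7760867017216539e+00	0
61	1.7778157174283198e+00	0
62	1.8072530749936291e+00	0
63	1.8831674381688048e+00	0
64	1.8940800113423635e+00	0
65	2.0169944289224353e+00	0
66	2.0341112493407723e+00	0
67	2.0789203657100819e+00	0
68	2.1043410485496459e+00	0
69	2.1230861573460733e+00	0
70	2.2575117296626335e+00	0
71	2.2889492120062513e+00	0
72	2.3089639398569490e+00	0
73	2.3119536349305903e+00	0
74	2.3857714844904439e+00	0
75	2.4938264658238607e+00	0
76	2.5310147811948474e+00	0
77	2.6151400103338349e+00	0
78	2.6908152708872191e+00	0
79	2.7078829783172056e+00	0
80	2.8319677762827347e+00	0
81	2.8354978944448987e+00	0
82	2.9801238460209811e+00	0
83	3.0149289274303435e+00	0
84	3.2954602773114896e+00	0
85	3.3629705334639701e+00	0
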