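# index	energy_hartree	occupied
0	-1.0246996252945882e+01	1
1	-1.0246675292842914e+01	1
2	-1.0242080684394990e+01	1
3	-1.0242054252328714e+01	1
4	-8.2036735804500005e-01	1
5	-7.3665821867671388e-01	1
6	-6.2493717041030450e-01	1
7	-5.6562685723439965e-01	1
8	-4.7664605831412443e-01	1
9	-4.7534245286902999e-01	1
10	-4.0259424517966180e-01	1
11	-3.9725741839292344e-01	1
12	-3.6795883493004278e-01	1
13	-3.3865282608709935e-01	1
14	-2.3683255804955244e-01	1
15	-4.1838185778791510e-02	0
16	7.3206775628159318e-02	0
17	9.2606856415966582e-02	0
18	9.9812976004178544e-02	0
19	1.0582584502344096e-01	0
20	1.5320453744155818e-01	0
21	1.6824750563009777e-01	0
22	1.7804919778873379e-01	0
23	2.9380033780433995e-01	0
24	3.1092382380980427e-01	0
25	3.6234185395531665e-01	0
26	4.0259459928390401e-01	0
27	4.2003648606413685e-01	0
28	4.3154021739177723e-01	0
29	4.5783345560242483e-01	0
30	4.9619544578964520e-01	0
31	5.3558426944983895e-01	0
32	5.4006528034334667e-01	0
33	5.5145039739392909e-01	0
34	6.1399508311826945e-01	0
35	6.2469856280412317e-01	0
36	6.6215150669810319e-01	0
37	6.7405608040445497e-01	0
38	6.8434239112481421e-01	0
39	6.8934455147696050e-01	0
40	7.1284944161757402e-01	0
41	7.1328566216974609e-01	0
42	7.7815624031706121e-01	0
43	8.1398128715561224e-01	0
44	8.3689608884723221e-01	0
45	1.0105476631891854e+00	0
46	1.1346526447401082e+00	0
47	1.1661288726546548e+00	0
48	1.1886205994228756e+00	0
49	1.2094604311027308e+00	0
50	1.2349471543250881e+00	0
51	1.2707523596789987e+00	0
52	1.2968651149946204e+00	0
53	1.6016563439293237e+00	0
54	1.6039064127402147e+00	0
55	1.6428077560361711e+00	0
56	1.6508630529427022e+00	0
57	1.6653113006440574e+00	0
58	1.7243301571874201e+00	0
59	1.7604443256453151e+00	0
60	1.7724328023941855e+00	0
61	1.7831227278190653e+00	0
62	1.8066659620432968e+00	0
63	1.8835287978603403e+00	0
64	1.8988540053382241e+00	0
65	2.0200574835845706e+00	0
66	2.0330854086716084e+00	0
67	2.0770743543533166e+00	0
68	2.1007046224197956e+00	0
69	2.1262921461344253e+00	0
70	2.2600553325449440e+00	0
71	2.2928452665833201e+00	0
72	2.3100191340380962e+00	0
73	2.3190125185423649e+00	0
74	2.3892999304027875e+00	0
75	2.4992120502399993e+00	0
76	2.5313458868647865e+00	0
77	2.6114490555794037e+00	0
78	2.6961344389885800e+00	0
79	2.7146824201169153e+00	0
80	2.8317878842573645e+00	0
81	2.8355810462825493e+00	0
82	2.9822875118739889e+00	0
83	3.0183485596991781e+00	0
84	3.3032140104609722e+00	0
85	3.3646459691641608e+00	0
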