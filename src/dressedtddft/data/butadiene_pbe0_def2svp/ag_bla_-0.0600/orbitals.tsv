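# index	energy_hartree	occupied
0	-1.0249155915903726e+01	1
1	-1.0248656936246968e+01	1
2	-1.0247453446834838e+01	1
3	-1.0247425998265992e+01	1
4	-8.2123380803630019e-01	1
5	-7.2775519359320795e-01	1
6	-6.3133510546772575e-01	1
7	-5.6596413668537571e-01	1
8	-4.7525214639633878e-01	1
9	-4.7246999039094217e-01	1
10	-4.0559745655208573e-01	1
11	-3.9358033882058202e-01	1
12	-3.7165090863474681e-01	1
13	-3.3884444767238553e-01	1
14	-2.2920543380739317e-01	1
15	-5.2595618854289823e-02	0
16	7.2115435112257043e-02	0
17	9.3331190343081988e-02	0
18	9.9845338257906480e-02	0
19	1.0486966049331987e-01	0
20	1.5182047645668431e-01	0
21	1.6564068818789834e-01	0
22	1.7961911033044950e-01	0
23	2.8409266941155026e-01	0
24	3.0357884412579078e-01	0
25	3.5979176404947666e-01	0
26	4.0023038705035757e-01	0
27	4.2888710582851014e-01	0
28	4.2953947814999577e-01	0
29	4.5773417661402221e-01	0
30	4.9761192521357694e-01	0
31	5.2712848345253238e-01	0
32	5.3958089093010142e-01	0
33	5.4803127917491290e-01	0
34	6.1674881167892548e-01	0
35	6.1890436683712102e-01	0
36	6.6129960041500657e-01	0
37	6.7414551469362161e-01	0
38	6.8274052843560917e-01	0
39	6.8817668507316143e-01	0
40	7.1105943987600362e-01	0
41	7.1297602416826322e-01	0
42	7.5112332313053409e-01	0
43	8.1810440814434593e-01	0
44	8.3578357407135095e-01	0
45	1.0057740141642755e+00	0
46	1.1211455137842108e+00	0
47	1.1659453631241474e+00	0
48	1.1925897939503389e+00	0
49	1.2085888485517708e+00	0
50	1.2267642250943729e+00	0
51	1.2708514926192764e+00	0
52	1.2955713165297271e+00	0
53	1.6012179938861262e+00	0
54	1.6044858536745190e+00	0
55	1.6371393170482902e+00	0
56	1.6393717512442751e+00	0
57	1.6620077829669830e+00	0
58	1.7256535664958372e+00	0
59	1.7523849377671750e+00	0
60	1.7632268005179483e+00	0
61	1.7919359073711358e+00	0
62	1.8104321157318790e+00	0
63	1.8806824518129299e+00	0
64	1.8826036106017223e+00	0
65	2.0086128351247394e+00	0
66	2.0372189180121110e+00	0
67	2.0840300297525065e+00	0
68	2.1132808382553367e+00	0
69	2.1142365489847323e+00	0
70	2.2506134392011607e+00	0
71	2.2780605037128208e+00	0
72	2.2915878851375671e+00	0
73	2.3063855273600762e+00	0
74	2.3755470204579008e+00	0
75	2.4786406839086319e+00	0
76	2.5319219511936208e+00	0
77	2.6270416849876379e+00	0
78	2.6757029056073178e+00	0
79	2.6908555855363545e+00	0
80	2.8336307386218453e+00	0
81	2.8360123740161809e+00	0
82	2.9742445479685578e+00	0
83	3.0050132927394690e+00	0
84	3.2732360688104754e+00	0
85	3.3590421109466275e+00	0
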