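# index	energy_hartree	occupied
0	-1.0248689324822820e+01	1
1	-1.0248239144114047e+01	1
2	-1.0246147837373460e+01	1
3	-1.0246121411251996e+01	1
4	-8.2088566354833570e-01	1
5	-7.2992349062136019e-01	1
6	-6.2980512075608130e-01	1
7	-5.6590052404090774e-01	1
8	-4.7559995314666942e-01	1
9	-4.7316665377529643e-01	1
10	-4.0485773927394736e-01	1
11	-3.9419270760592245e-01	1
12	-3.7113412336811358e-01	1
13	-3.3871583135620448e-01	1
14	-2.3106772507907028e-01	1
15	-4.9959528498104921e-02	0
16	7.2270369233757459e-02	0
17	9.3166699923858898e-02	0
18	9.9840691613968094e-02	0
19	1.0512959353452768e-01	0
20	1.5220875391413369e-01	0
21	1.6628360059569311e-01	0
22	1.7931802655629905e-01	0
23	2.8720826802377730e-01	0
24	3.0539245069380005e-01	0
25	3.5988221603591575e-01	0
26	4.0109367369988030e-01	0
27	4.2676141324325106e-01	0
28	4.2973081057048262e-01	0
29	4.5766477517066018e-01	0
30	4.9739810857785999e-01	0
31	5.2928636326254941e-01	0
32	5.3972892395894967e-01	0
33	5.4884068141913334e-01	0
34	6.1598759435583639e-01	0
35	6.2031930470094843e-01	0
36	6.6156723352976909e-01	0
37	6.7415013881446251e-01	0
38	6.8326332675191925e-01	0
39	6.8876459060609319e-01	0
40	7.1132148220631097e-01	0
41	7.1308627827469118e-01	0
42	7.5702959112498447e-01	0
43	8.1951026496065282e-01	0
44	8.3266841059259977e-01	0
45	1.0072686892128986e+00	0
46	1.1244136315969910e+00	0
47	1.1655075051884116e+00	0
48	1.1916202446939428e+00	0
49	1.2088350069521092e+00	0
50	1.2286287499473392e+00	0
51	1.2706858240522534e+00	0
52	1.2954800129244413e+00	0
53	1.6017283073111761e+00	0
54	1.6043880648428244e+00	0
55	1.6395363057355548e+00	0
56	1.6427495567424455e+00	0
57	1.6629810334523449e+00	0
58	1.7253659171603788e+00	0
59	1.7543237064379296e+00	0
60	1.7678104710180742e+00	0
61	1.7859773765814315e+00	0
62	1.8091621389508830e+00	0
63	1.8827067688626438e+00	0
64	1.8849822600937967e+00	0
65	2.0112671849654169e+00	0
66	2.0361795923572794e+00	0
67	2.0824043019419607e+00	0
68	2.1111283744248937e+00	0
69	2.1165794905090474e+00	0
70	2.2527932384128846e+00	0
71	2.2815567912231662e+00	0
72	2.2982187774036484e+00	0
73	2.3071489251261124e+00	0
74	2.3788884052441901e+00	0
75	2.4835368748945266e+00	0
76	2.5313024664162564e+00	0
77	2.6230063607050704e+00	0
78	2.6805918943589786e+00	0
79	2.6958970079597608e+00	0
80	2.8329011405208897e+00	0
81	2.8357378139255651e+00	0
82	2.9760980235326362e+00	0
83	3.0082683186056527e+00	0
84	3.2804575706338901e+00	0
85	3.3601698556952204e+00	0
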