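# index	energy_hartree	occupied
0	-1.0249577068448648e+01	1
1	-1.0249041712444418e+01	1
2	-1.0248727919498400e+01	1
3	-1.0248683204404808e+01	1
4	-8.2166862872247715e-01	1
5	-7.2562648406863695e-01	1
6	-6.3281645601763570e-01	1
7	-5.6601343769002554e-01	1
8	-4.7490370322746456e-01	1
9	-4.7178631883341626e-01	1
10	-4.0632925820891641e-01	1
11	-3.9324222784088875e-01	1
12	-3.7182758242194874e-01	1
13	-3.3902694994699567e-01	1
14	-2.2737306371423516e-01	1
15	-5.5195155480992367e-02	0
16	7.2041147552277848e-02	0
17	9.3485372248203233e-02	0
18	9.9847958721255362e-02	0
19	1.0459319355639300e-01	0
20	1.5139905629087202e-01	0
21	1.6500695898350234e-01	0
22	1.7986377285779584e-01	0
23	2.8057062398484439e-01	0
24	3.0178340450384844e-01	0
25	3.6003241379262935e-01	0
26	3.9919597587296451e-01	0
27	4.2954144854538540e-01	0
28	4.3092347514350693e-01	0
29	4.5788639643575924e-01	0
30	4.9773140492959339e-01	0
31	5.2495031823046046e-01	0
32	5.3941874104213172e-01	0
33	5.4725343355147227e-01	0
34	6.1751256052701553e-01	0
35	6.1755655831635070e-01	0
36	6.6099060800761111e-01	0
37	6.7411453633530127e-01	0
38	6.8211792267964255e-01	0
39	6.8740354863748765e-01	0
40	7.1097864205745254e-01	0
41	7.1268649096771619e-01	0
42	7.4588923281008257e-01	0
43	8.1594657758104305e-01	0
44	8.4029013452122014e-01	0
45	1.0040841902081616e+00	0
46	1.1179492191601328e+00	0
47	1.1666998128878188e+00	0
48	1.1935369108207765e+00	0
49	1.2083224235725478e+00	0
50	1.2250217065288647e+00	0
51	1.2711094784161974e+00	0
52	1.2959468581976346e+00	0
53	1.6003386720723403e+00	0
54	1.6045423476741405e+00	0
55	1.6343455045929234e+00	0
56	1.6356458081588972e+00	0
57	1.6609361572074535e+00	0
58	1.7259590750476752e+00	0
59	1.7505004755213831e+00	0
60	1.7589704895553764e+00	0
61	1.7983821431491218e+00	0
62	1.8118951246934503e+00	0
63	1.8765651682904456e+00	0
64	1.8825824292723892e+00	0
65	2.0061023863808898e+00	0
66	2.0382594735451711e+00	0
67	2.0855714843358237e+00	0
68	2.1099531906496054e+00	0
69	2.1171238473345335e+00	0
70	2.2485498953979692e+00	0
71	2.2746962722365316e+00	0
72	2.2851470542627870e+00	0
73	2.3057153911428858e+00	0
74	2.3722802325585581e+00	0
75	2.4739156836696528e+00	0
76	2.5328592747885925e+00	0
77	2.6309577263339161e+00	0
78	2.6709666828928129e+00	0
79	2.6866379438473071e+00	0
80	2.8345218913717245e+00	0
81	2.8363647290870677e+00	0
82	2.9725042346996564e+00	0
83	3.0018006057799247e+00	0
84	3.2662207551076028e+00	0
85	3.3580933585650254e+00	0
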