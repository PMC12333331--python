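# index	energy_hartree	occupied
0	-1.0250091686072887e+01	1
1	-1.0249994721398028e+01	1
2	-1.0249830860119555e+01	1
3	-1.0249289980650497e+01	1
4	-8.2218902168922536e-01	1
5	-7.2353801041262245e-01	1
6	-6.3424803605978330e-01	1
7	-5.6604820640124109e-01	1
8	-4.7455391718572559e-01	1
9	-4.7111486605842051e-01	1
10	-4.0705283589657182e-01	1
11	-3.9319627434746973e-01	1
12	-3.7164648429560421e-01	1
13	-3.3926338084410157e-01	1
14	-2.2557080544000796e-01	1
15	-5.7757478201778671e-02	0
16	7.2048705662682302e-02	0
17	9.3629645133397485e-02	0
18	9.9848667267646754e-02	0
19	1.0429823287084820e-01	0
20	1.5094121178981751e-01	0
21	1.6438477400671531e-01	0
22	1.8005449422901065e-01	0
23	2.7668882641034959e-01	0
24	3.0000813421010147e-01	0
25	3.6056837292518540e-01	0
26	3.9800564655095111e-01	0
27	4.2972031581313047e-01	0
28	4.3285187447344053e-01	0
29	4.5813655154219285e-01	0
30	4.9775629538588867e-01	0
31	5.2275793013114591e-01	0
32	5.3924449885829029e-01	0
33	5.4650710938649094e-01	0
34	6.1614442903812860e-01	0
35	6.1841010972764932e-01	0
36	6.6063257221520322e-01	0
37	6.7405063332279236e-01	0
38	6.8138647826430687e-01	0
39	6.8647008401831233e-01	0
40	7.1105487560386682e-01	0
41	7.1215235758929607e-01	0
42	7.4140608266076247e-01	0
43	8.1360856972562712e-01	0
44	8.4561419879102762e-01	0
45	1.0022062242993561e+00	0
46	1.1148246429851119e+00	0
47	1.1677629752655359e+00	0
48	1.1944571282400858e+00	0
49	1.2080349621684150e+00	0
50	1.2234014542407441e+00	0
51	1.2714577931273705e+00	0
52	1.2966112533413678e+00	0
53	1.5989868991732745e+00	0
54	1.6045442761764992e+00	0
55	1.6313503560728067e+00	0
56	1.6315840603082483e+00	0
57	1.6597663289348707e+00	0
58	1.7262975801966618e+00	0
59	1.7486728528334461e+00	0
60	1.7550623025130414e+00	0
61	1.8051876772857962e+00	0
62	1.8135430977316529e+00	0
63	1.8726449150610427e+00	0
64	1.8826409446143633e+00	0
65	2.0037379167374811e+00	0
66	2.0392995191683618e+00	0
67	2.0870242014187528e+00	0
68	2.1065974048280549e+00	0
69	2.1197657705994586e+00	0
70	2.2466000092801766e+00	0
71	2.2714623988675631e+00	0
72	2.2789224140706517e+00	0
73	2.3051360430216210e+00	0
74	2.3690931679768563e+00	0
75	2.4693661286426605e+00	0
76	2.5341150941403097e+00	0
77	2.6344954198539159e+00	0
78	2.6663833379350268e+00	0
79	2.6835038520079926e+00	0
80	2.8355652140135112e+00	0
81	2.8367800777417425e+00	0
82	2.9708832239398313e+00	0
83	2.9986254286762541e+00	0
84	3.2594275315291070e+00	0
85	3.3573207683449500e+00	0
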