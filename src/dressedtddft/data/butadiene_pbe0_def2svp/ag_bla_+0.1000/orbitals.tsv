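# index	energy_hartree	occupied
0	-1.0244086357439546e+01	1
1	-1.0243898922174507e+01	1
2	-1.0236337148773488e+01	1
3	-1.0236310377335199e+01	1
4	-8.2089936248989237e-01	1
5	-7.4613821908332678e-01	1
6	-6.1786031628276494e-01	1
7	-5.6508385037483155e-01	1
8	-4.7847385650076663e-01	1
9	-4.7806827620699316e-01	1
10	-4.0275343999708296e-01	1
11	-3.9948491649653856e-01	1
12	-3.6138004243167976e-01	1
13	-3.3931979649919380e-01	1
14	-2.4493045549939862e-01	1
15	-3.0533535188702970e-02	0
16	7.5509556902191077e-02	0
17	9.1685150633052034e-02	0
18	9.9735649394135720e-02	0
19	1.0659920768024493e-01	0
20	1.5422778493075701e-01	0
21	1.7089703553618718e-01	0
22	1.7540038605361974e-01	0
23	2.9639396934627693e-01	0
24	3.1845105059207018e-01	0
25	3.6991571038214605e-01	0
26	4.0240589308999392e-01	0
27	4.1111753438335608e-01	0
28	4.3653973083496239e-01	0
29	4.5864066862833591e-01	0
30	4.9331192583252731e-01	0
31	5.4016076506691180e-01	0
32	5.4340658553715326e-01	0
33	5.5527859111442091e-01	0
34	6.1208950150465513e-01	0
35	6.3084375767680401e-01	0
36	6.6233732494138875e-01	0
37	6.7382752418218939e-01	0
38	6.8506511353566657e-01	0
39	6.8796641662549585e-01	0
40	7.1229736397074161e-01	0
41	7.1816284132748898e-01	0
42	8.0281551839402165e-01	0
43	8.1286617417363827e-01	0
44	8.5508333213105459e-01	0
45	1.0122067332411031e+00	0
46	1.1493394230338070e+00	0
47	1.1713384313152484e+00	0
48	1.1845461013069156e+00	0
49	1.2100556173686416e+00	0
50	1.2450211000275277e+00	0
51	1.2721270887895011e+00	0
52	1.3024383112936118e+00	0
53	1.5982651070363418e+00	0
54	1.6029062961676472e+00	0
55	1.6356203392613362e+00	0
56	1.6577734529417747e+00	0
57	1.6670603138129214e+00	0
58	1.7218279523877562e+00	0
59	1.7679398943726876e+00	0
60	1.7692538952393393e+00	0
61	1.8010409371871288e+00	0
62	1.8112190217810857e+00	0
63	1.8858855466351838e+00	0
64	1.9191535892390930e+00	0
65	2.0290734352933115e+00	0
66	2.0334074305670682e+00	0
67	2.0692343971306215e+00	0
68	2.0849881727134698e+00	0
69	2.1387714786819561e+00	0
70	2.2715125968322627e+00	0
71	2.3097148260930882e+00	0
72	2.3152566650650983e+00	0
73	2.3480526328523035e+00	0
74	2.4038098154498493e+00	0
75	2.5222762869510276e+00	0
76	2.5358417003888651e+00	0
77	2.5987928083696801e+00	0
78	2.7183558031507098e+00	0
79	2.7466037424577361e+00	0
80	2.8334069642267408e+00	0
81	2.8381193994710592e+00	0
82	2.9918699816624592e+00	0
83	3.0328361112581605e+00	0
84	3.3356196554519193e+00	0
85	3.3731817170281220e+00	0
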