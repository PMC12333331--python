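# index	energy_hartree	occupied
0	-1.0245261107840291e+01	1
1	-1.0245028192973288e+01	1
2	-1.0238531803754086e+01	1
3	-1.0238505158588310e+01	1
4	-8.2053823322157371e-01	1
5	-7.4252006264572545e-01	1
6	-6.2058634733388207e-01	1
7	-5.6530970516677370e-01	1
8	-4.7752957915633126e-01	1
9	-4.7726589670979946e-01	1
10	-4.0066202040172405e-01	1
11	-4.0060109064530752e-01	1
12	-3.6406455500302687e-01	1
13	-3.3896934387410244e-01	1
14	-2.4183883655779545e-01	1
15	-3.4834793075415565e-02	0
16	7.4509058907501785e-02	0
17	9.2056424821724409e-02	0
18	9.9770936383379721e-02	0
19	1.0632735050233466e-01	0
20	1.5387799151084108e-01	0
21	1.6990251531171410e-01	0
22	1.7653111909945277e-01	0
23	2.9613585248805235e-01	0
24	3.1561274764595865e-01	0
25	3.6669050978758694e-01	0
26	4.0270896519192045e-01	0
27	4.1435315603118522e-01	0
28	4.3437411310834106e-01	0
29	4.5827918463126621e-01	0
30	4.9456126049485294e-01	0
31	5.4018256326391800e-01	0
32	5.4056307368811607e-01	0
33	5.5380607059057108e-01	0
34	6.1269514459470853e-01	0
35	6.2849831758980457e-01	0
36	6.6236495865771206e-01	0
37	6.7391513533563863e-01	0
38	6.8485015204673627e-01	0
39	6.8868446717395160e-01	0
40	7.1247279305892020e-01	0
41	7.1610666240324417e-01	0
42	7.9906120201172059e-01	0
43	8.0666865395990572e-01	0
44	8.4744736263176468e-01	0
45	1.0119240052572689e+00	0
46	1.1436912452942247e+00	0
47	1.1688277728101588e+00	0
48	1.1860737833443293e+00	0
49	1.2098627753709150e+00	0
50	1.2410271117574792e+00	0
51	1.2714458728510409e+00	0
52	1.2998603255195540e+00	0
53	1.6000459878307232e+00	0
54	1.6033258175346163e+00	0
55	1.6397922134518415e+00	0
56	1.6556138368759099e+00	0
57	1.6665836996706132e+00	0
58	1.7228816133471720e+00	0
59	1.7658679063132077e+00	0
60	1.7677674779522601e+00	0
61	1.7960922099391647e+00	0
62	1.8071543900421772e+00	0
63	1.8848278296453891e+00	0
64	1.9113449855445441e+00	0
65	2.0282297354666210e+00	0
66	2.0305574529979400e+00	0
67	2.0722261990495343e+00	0
68	2.0910622805319981e+00	0
69	2.1341594578034910e+00	0
70	2.2669707988743126e+00	0
71	2.3031555830424448e+00	0
72	2.3130994444995214e+00	0
73	2.3370529805605336e+00	0
74	2.3983134125628514e+00	0
75	2.5133491203333289e+00	0
76	2.5335596353173666e+00	0
77	2.6031344608777096e+00	0
78	2.7099089989891443e+00	0
79	2.7337844674124723e+00	0
80	2.8323049041381623e+00	0
81	2.8366508553723664e+00	0
82	2.9881084753250065e+00	0
83	3.0272279287279504e+00	0
84	3.3232325670944078e+00	0
85	3.3696387264916590e+00	0
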