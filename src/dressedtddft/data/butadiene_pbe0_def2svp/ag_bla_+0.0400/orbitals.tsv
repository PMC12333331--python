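# index	energy_hartree	occupied
0	-1.0246336499986914e+01	1
1	-1.0246052722089734e+01	1
2	-1.0240677924855355e+01	1
3	-1.0240651408182810e+01	1
4	-8.2037035317849627e-01	1
5	-7.3897677138630946e-01	1
6	-6.2322716303623094e-01	1
7	-5.6550927370163429e-01	1
8	-4.7699765119741316e-01	1
9	-4.7609898558055869e-01	1
10	-4.0182604330673594e-01	1
11	-3.9854227524468144e-01	1
12	-3.6650397601752582e-01	1
13	-3.3873924535562461e-01	1
14	-2.3881308525128050e-01	1
15	-3.9061996218939063e-02	0
16	7.3671985489427785e-02	0
17	9.2396420525811346e-02	0
18	9.9798468060663781e-02	0
19	1.0603414250485538e-01	0
20	1.5348879915360444e-01	0
21	1.6890861931712706e-01	0
22	1.7749501312924992e-01	0
23	2.9505595277693319e-01	0
24	3.1279220930968227e-01	0
25	3.6387099164605824e-01	0
26	4.0274886059561565e-01	0
27	4.1774674135667594e-01	0
28	4.3254304473783806e-01	0
29	4.5798496957373430e-01	0
30	4.9560980616614397e-01	0
31	5.3760921889114166e-01	0
32	5.4013285975907666e-01	0
33	5.5237541288225911e-01	0
34	6.1343357468573390e-01	0
35	6.2620216196117717e-01	0
36	6.6227074839168909e-01	0
37	6.7400282040836301e-01	0
38	6.8457676044685833e-01	0
39	6.8918105899394944e-01	0
40	7.1269638800867197e-01	0
41	7.1430558374292519e-01	0
42	7.8618775083382419e-01	0
43	8.1095881560070715e-01	0
44	8.4074829697111153e-01	0
45	1.0112410542373820e+00	0
46	1.1382122810558395e+00	0
47	1.1669769219070192e+00	0
48	1.1876036624365265e+00	0
49	1.2096337627847975e+00	0
50	1.2372915183735695e+00	0
51	1.2709616197155686e+00	0
52	1.2978658546563664e+00	0
53	1.6011859987078849e+00	0
54	1.6036924269975616e+00	0
55	1.6422528086125641e+00	0
56	1.6529570132338327e+00	0
57	1.6658926734927011e+00	0
58	1.7238233134060277e+00	0
59	1.7625799656548846e+00	0
60	1.7697842476391032e+00	0
61	1.7884975731244455e+00	0
62	1.8064098438046678e+00	0
63	1.8839798257024847e+00	0
64	1.9037616160996016e+00	0
65	2.0232438447076819e+00	0
66	2.0320671827306573e+00	0
67	2.0751693957815083e+00	0
68	2.0969329268280896e+00	0
69	2.1294650437980138e+00	0
70	2.2627249967735890e+00	0
71	2.2968729760571898e+00	0
72	2.3111748027646035e+00	0
73	2.3261710522226697e+00	0
74	2.3928764658662551e+00	0
75	2.5047532211615189e+00	0
76	2.5319935837488297e+00	0
77	2.6079617463733591e+00	0
78	2.7015738077691362e+00	0
79	2.7219716870864250e+00	0
80	2.8318188537811668e+00	0
81	2.8358409432248988e+00	0
82	2.9845468069428907e+00	0
83	3.0218387740644426e+00	0
84	3.3111187818774930e+00	0
85	3.3665054096080631e+00	0
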