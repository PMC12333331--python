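# index	energy_hartree	occupied
0	-1.0248173601941042e+01	1
1	-1.0247769589741404e+01	1
2	-1.0244816347016576e+01	1
3	-1.0244790032713682e+01	1
4	-8.2062496602293211e-01	1
5	-7.3213064577684672e-01	1
6	-6.2822780648297571e-01	1
7	-5.6582287833427913e-01	1
8	-4.7594779067548021e-01	1
9	-4.7387709022831503e-01	1
10	-4.0411041893640026e-01	1
11	-3.9504072562398396e-01	1
12	-3.7031560794161716e-01	1
13	-3.3864105628387059e-01	1
14	-2.3295976907667074e-01	1
15	-4.7287522069664009e-02	0
16	7.2504728589782172e-02	0
17	9.2991467042993159e-02	0
18	9.9833871638240548e-02	0
19	1.0537468003486287e-01	0
20	1.5256698838244773e-01	0
21	1.6693356636580295e-01	0
22	1.7895787037044711e-01	0
23	2.8987871392372905e-01	0
24	3.0722232503117730e-01	0
25	3.6033138413761784e-01	0
26	4.0177592660272071e-01	0
27	4.2456496437377533e-01	0
28	4.3012665659706956e-01	0
29	4.5766516242205241e-01	0
30	4.9709036235932902e-01	0
31	5.3141833140589956e-01	0
32	5.3986063047396216e-01	0
33	5.4968113669766705e-01	0
34	6.1527394192515972e-01	0
35	6.2175689653444088e-01	0
36	6.6179782673650700e-01	0
37	6.7413376489812060e-01	0
38	6.8369703714862162e-01	0
39	6.8915340726083751e-01	0
40	7.1177988159873140e-01	0
41	7.1307400283074218e-01	0
42	7.6353880827148313e-01	0
43	8.1911762339412098e-01	0
44	8.3199112051669555e-01	0
45	1.0085634936031285e+00	0
46	1.1277538803928748e+00	0
47	1.1653913269215650e+00	0
48	1.1906327142358282e+00	0
49	1.2090617668221371e+00	0
50	1.2306146746019562e+00	0
51	1.2706138265312907e+00	0
52	1.2956682037310132e+00	0
53	1.6019435293447866e+00	0
54	1.6042563254980118e+00	0
55	1.6413671599891995e+00	0
56	1.6457812782237611e+00	0
57	1.6638559011729150e+00	0
58	1.7250716214792070e+00	0
59	1.7563145080262434e+00	0
60	1.7726889811009097e+00	0
61	1.7806461733014567e+00	0
62	1.8080964340222685e+00	0
63	1.8828940455348759e+00	0
64	1.8894520872666549e+00	0
65	2.0140624367724236e+00	0
66	2.0351431660724315e+00	0
67	2.0806992180961648e+00	0
68	2.1078225530966685e+00	0
69	2.1198482519505699e+00	0
70	2.2550918390164516e+00	0
71	2.2851862337573277e+00	0
72	2.3050150945419809e+00	0
73	2.3080077600912059e+00	0
74	2.3822986669565918e+00	0
75	2.4886001306716787e+00	0
76	2.5310002277508157e+00	0
77	2.6190090281522127e+00	0
78	2.6856312049607132e+00	0
79	2.7016035894009858e+00	0
80	2.8323431224351139e+00	0
81	2.8355590297404429e+00	0
82	2.9780593351022180e+00	0
83	3.0115713467867575e+00	0
84	3.2878703378132004e+00	0
85	3.3614788055505755e+00	0
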