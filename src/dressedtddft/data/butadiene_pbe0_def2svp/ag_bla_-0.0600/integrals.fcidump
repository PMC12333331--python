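&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6879439475881221E-01    1    1    1    1
 6.3163883845529512E-14    2    1    1    1
 9.4026894699874158E-02    2    1    2    1
 3.0814969231945599E-01    2    2    1    1
-4.5831394235307243E-14    2    2    2    1
 3.1844291804424796E-01    2    2    2    2
-5.7130131639733225E-02    3    1    1    1
 8.7119547687031229E-14    3    1    2    1
 9.3363830581613648E-03    3    1    2    2
 6.2764527699451428E-02    3    1    3    1
 1.3703144521870492E-13    3    2    1    1
 6.6735467304078783E-02    3    2    2    1
 1.9356044544949214E-14    3    2    2    2
 4.3892840750903162E-14    3    2    3    1
 9.9872639431327848E-02    3    2    3    2
 3.0700750894658169E-01    3    3    1    1
 2.1625062851526877E-14    3    3    2    1
 3.0907189236111587E-01    3    3    2    2
 1.8454380162350598E-03    3    3    3    1
-4.3604009292153023E-14    3    3    3    2
 3.0948071426311352E-01    3    3    3    3
-4.6056040925446240E-14    4    1    1    1
-2.9168006950022352E-02    4    1    2    1
 8.6696275158892888E-14    4    1    2    2
 8.7837723206085627E-14    4    1    3    1
 3.1585103578864224E-02    4    1    3    2
-6.8625660709642489E-14    4    1    3    3
 6.4341468737284135E-02    4    1    4    1
-5.1996396195632275E-02    4    2    1    1
 1.1311437897454368E-13    4    2    2    1
 2.2422259902204322E-03    4    2    2    2
 5.2175849882746671E-02    4    2    3    1
-6.0370979049206852E-14    4    2    3    2
 3.0387822590968597E-03    4    2    3    3
-7.4605686212203537E-14    4    2    4    1
 5.0135136739686323E-02    4    2    4    2
 1.8801106504984233E-13    4    3    1    1
 7.8616612141131692E-02    4    3    2    1
-5.9112437167385679E-14    4    3    2    2
-7.7684386701193375E-14    4    3    3    1
 5.7091138079463893E-02    4    3    3    2
 1.3395534681492904E-14    4    3    3    3
-2.7325744524874015E-02    4    3    4    1
-3.2258917759264705E-14    4    3    4    2
 7.4284822957687235E-02    4    3    4    3
 3.4168367887573892E-01    4    4    1    1
-1.5979231826612761E-13    4    4    2    1
 2.9108407413849208E-01    4    4    2    2
-4.9624421689240805E-02    4    4    3    1
-5.2242932202517522E-14    4    4    3    2
 2.9117736149124385E-01    4    4    3    3
 1.2854300956988141E-14    4    4    4    1
-4.7671223494104416E-02    4    4    4    2
-1.9945850526781328E-14    4    4    4    3
 3.2966934228514633E-01    4    4    4    4
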