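&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6164626047638271E-01    1    1    1    1
-2.7854454853759592E-14    2    1    1    1
 1.0321972584540232E-01    2    1    2    1
 3.1534361379777859E-01    2    2    1    1
 2.8099050863872321E-14    2    2    2    1
 3.2206003987804521E-01    2    2    2    2
-5.1314867694365392E-02    3    1    1    1
-1.6531914726058972E-15    3    1    2    1
 6.3790969860193537E-03    3    1    2    2
 6.3528709984275664E-02    3    1    3    1
-6.7298597250520231E-15    3    2    1    1
 6.3193454982202094E-02    3    2    2    1
 2.8284666275801840E-14    3    2    2    2
-1.1646933417708283E-14    3    2    3    1
 9.0871616925340945E-02    3    2    3    2
 3.1022331239028511E-01    3    3    1    1
-2.3685914340987324E-14    3    3    2    1
 3.0970502190233185E-01    3    3    2    2
-6.0938835665549224E-04    3    3    3    1
-2.0032586700580168E-14    3    3    3    2
 3.0866303631540715E-01    3    3    3    3
-1.6518904299989146E-14    4    1    1    1
 2.6457909087849993E-02    4    1    2    1
-3.8510861166685117E-15    4    1    2    2
 9.4386304327898074E-15    4    1    3    1
-3.5704942447681853E-02    4    1    3    2
-7.0603245472256049E-16    4    1    3    3
 6.1153814489762474E-02    4    1    4    1
 4.9052010185061307E-02    4    2    1    1
-8.8973967082850436E-15    4    2    2    1
 1.6122920778207425E-03    4    2    2    2
-5.3830517428050312E-02    4    2    3    1
-1.2136125437933742E-14    4    2    3    2
 1.5948038244094527E-04    4    2    3    3
 4.8988590961585032E-15    4    2    4    1
 5.2081191953595993E-02    4    2    4    2
 1.6538853619962879E-14    4    3    1    1
-8.5228252181764330E-02    4    3    2    1
-2.4537663567691936E-14    4    3    2    2
 7.0030786725183702E-15    4    3    3    1
-5.3567825268233116E-02    4    3    3    2
 1.9916360227689722E-14    4    3    3    3
-2.4370045528602838E-02    4    3    4    1
 2.2759572004815709E-15    4    3    4    2
 7.9598617955826956E-02    4    3    4    3
 3.3484564434596303E-01    4    4    1    1
 9.9607821990588263E-15    4    4    2    1
 2.9575885495727477E-01    4    4    2    2
-4.5406002299538444E-02    4    4    3    1
 5.4123372450476381E-15    4    4    3    2
 2.9365443389883250E-01    4    4    3    3
 5.0098813986210189E-15    4    4    4    1
 4.5104739996123883E-02    4    4    4    2
-1.5768636396629176E-14    4    4    4    3
 3.2279267191068128E-01    4    4    4    4
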