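&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6638874927355430E-01    1    1    1    1
 1.0253603521803711E-13    2    1    1    1
 9.6852741492844868E-02    2    1    2    1
 3.1036412161651089E-01    2    2    1    1
-8.1344653235504438E-14    2    2    2    1
 3.1943750675056742E-01    2    2    2    2
-5.5374594520832585E-02    3    1    1    1
 1.1794298176992513E-13    3    1    2    1
 8.4320246175468953E-03    3    1    2    2
 6.3091915053248640E-02    3    1    3    1
 1.8490504266610586E-13    3    2    1    1
 6.5735350093846470E-02    3    2    2    1
 1.4394735403655545E-14    3    2    2    2
 6.8722805224297190E-14    3    2    3    1
 9.7050043457427210E-02    3    2    3    2
 3.0806926797237449E-01    3    3    1    1
 4.8894915893882285E-14    3    3    2    1
 3.0922617265046293E-01    3    3    2    2
 1.0758418886132187E-03    3    3    3    1
-3.8781478028937499E-14    3    3    3    2
 3.0923954573196688E-01    3    3    3    3
-5.4996805720630704E-14    4    1    1    1
-2.8385517221430540E-02    4    1    2    1
 1.1785537823438830E-13    4    1    2    2
 1.1846426617445616E-13    4    1    3    1
 3.2931125460066296E-02    4    1    3    2
-9.2243053473328729E-14    4    1    3    3
 6.3348579805384650E-02    4    1    4    1
-5.1142987462785061E-02    4    2    1    1
 1.4634387451861741E-13    4    2    2    1
 1.0714323966300072E-03    4    2    2    2
 5.2775135302348494E-02    4    2    3    1
-8.9369484035373148E-14    4    2    3    2
 2.0517008510912409E-03    4    2    3    3
-1.0657100202315917E-13    4    2    4    1
 5.0819425511934364E-02    4    2    4    2
 2.5738525893936881E-13    4    3    1    1
 8.0707208373529987E-02    4    3    2    1
-9.3642975318442012E-14    4    3    2    2
-1.0189245280844972E-13    4    3    3    1
 5.6091536461203559E-02    4    3    3    2
 3.7310432521309167E-14    4    3    3    3
-2.6472869770532998E-02    4    3    4    1
-4.7833265126584479E-14    4    3    4    2
 7.6001428992582151E-02    4    3    4    3
 3.3951814044411444E-01    4    4    1    1
-2.2642998587230068E-13    4    4    2    1
 2.9259689373532205E-01    4    4    2    2
-4.8386844228648751E-02    4    4    3    1
-7.8298478811689165E-14    4    4    3    2
 2.9205470510509401E-01    4    4    3    3
 2.6575963651964685E-14    4    4    4    1
-4.6952623322705819E-02    4    4    4    2
-4.5220771571763407E-14    4    4    4    3
 3.2757180837699312E-01    4    4    4    4
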