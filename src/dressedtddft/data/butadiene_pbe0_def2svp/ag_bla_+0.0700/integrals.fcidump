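&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.5996981770141734E-01    1    1    1    1
-6.6615983562723358E-14    2    1    1    1
 1.0585416565481429E-01    2    1    2    1
 3.1740442680264697E-01    2    2    1    1
 6.1131655293422682E-14    2    2    2    1
 3.2330568001667681E-01    2    2    2    2
-4.9605133646720312E-02    3    1    1    1
-3.9994049738645288E-14    3    1    2    1
 5.5345251111129125E-03    3    1    2    2
 6.3585900245124130E-02    3    1    3    1
-6.3306131170559610E-14    3    2    1    1
 6.2036801238096850E-02    3    2    2    1
 2.2830695667330758E-14    3    2    2    2
-3.2356062273919406E-14    3    2    3    1
 8.8397250501087321E-02    3    2    3    2
 3.1101765823609528E-01    3    3    1    1
-3.8843928074072664E-14    3    3    2    1
 3.0995177929939932E-01    3    3    2    2
-1.2791158744501971E-03    3    3    3    1
-7.5703332491627862E-15    3    3    3    2
 3.0840265112207244E-01    3    3    3    3
-2.7150157122513008E-14    4    1    1    1
 2.5605171840786853E-02    4    1    2    1
 3.1336912231783032E-14    4    1    2    2
 4.4549433586560383E-14    4    1    3    1
-3.6736068367249797E-02    4    1    3    2
-2.9164171078122081E-14    4    1    3    3
 6.0265915636626616E-02    4    1    4    1
 4.8129180324726427E-02    4    2    1    1
 3.4925187741841057E-14    4    2    2    1
 2.7302064922435608E-03    4    2    2    2
-5.4141907440247411E-02    4    2    3    1
-4.0833655901018062E-14    4    2    3    2
 1.0589369657172214E-03    4    2    3    3
 3.4104229856835033E-14    4    2    4    1
 5.2481551832176856E-02    4    2    4    2
 9.5275350109336188E-14    4    3    1    1
-8.7011695075451728E-02    4    3    2    1
-5.6626578426310914E-14    4    3    2    2
-2.2707530300536405E-14    4    3    3    1
-5.2424325632059822E-02    4    3    3    2
 3.3393426912553537E-14    4    3    3    3
-2.3438300353200284E-02    4    3    4    1
 1.9369922332757028E-14    4    3    4    2
 8.0963917095509680E-02    4    3    4    3
 3.3300280624637135E-01    4    4    1    1
 7.5092709828084026E-14    4    4    2    1
 2.9695828019379633E-01    4    4    2    2
-4.4106430118550283E-02    4    4    3    1
 2.9531932455029164E-14    4    4    3    2
 2.9415556681632649E-01    4    4    3    3
 3.8372083288606973E-15    4    4    4    1
 4.4255131300430454E-02    4    4    4    2
-2.9479890750749860E-14    4    4    4    3
 3.2079913160702478E-01    4    4    4    4
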