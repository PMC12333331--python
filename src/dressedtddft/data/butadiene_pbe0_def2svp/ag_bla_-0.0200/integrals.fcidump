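&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6563762494507485E-01    1    1    1    1
 3.8071108765524997E-14    2    1    1    1
 9.7781655827058139E-02    2    1    2    1
 3.1109116932110192E-01    2    2    1    1
-2.5153490401663703E-14    2    2    2    1
 3.1978673214318026E-01    2    2    2    2
-5.4790517915720913E-02    3    1    1    1
 4.2578787717850730E-14    3    1    2    1
 8.1331177771584266E-03    3    1    2    2
 6.3181744182503080E-02    3    1    3    1
 6.6183603736336138E-14    3    2    1    1
 6.5388666272382934E-02    3    2    2    1
 1.2431028428849800E-14    3    2    2    2
 3.0806086848134129E-14    3    2    3    1
 9.6132427282403662E-02    3    2    3    2
 3.0840412178333987E-01    3    3    1    1
 2.7595981055839047E-14    3    3    2    1
 3.0928495377965121E-01    3    3    2    2
 8.2524451963621182E-04    3    3    3    1
-7.8756445809347042E-15    3    3    3    2
 3.0915882961344349E-01    3    3    3    3
-1.6577884898172357E-14    4    1    1    1
-2.8117777085422950E-02    4    1    2    1
 4.3776614278012715E-14    4    1    2    2
 4.4562010331761215E-14    4    1    3    1
 3.3358949997031727E-02    4    1    3    2
-3.8203815111437223E-14    4    1    3    3
 6.3024481480335445E-02    4    1    4    1
-5.0851780460065950E-02    4    2    1    1
 5.2507477532603986E-14    4    2    2    1
 6.8313752395565697E-04    4    2    2    2
 5.2954975859472897E-02    4    2    3    1
-3.2926786297515775E-14    4    2    3    2
 1.7273265281751412E-03    4    2    3    3
-4.2479041117982064E-14    4    2    4    1
 5.1028255726758932E-02    4    2    4    2
 9.8599947651045738E-14    4    3    1    1
 8.1383830754313616E-02    4    3    2    1
-3.0569297093663295E-14    4    3    2    2
-4.3437475838459250E-14    4    3    3    1
 5.5746121193995371E-02    4    3    3    2
 2.2265175814162319E-14    4    3    3    3
-2.6180984514619452E-02    4    3    4    1
-2.3873264476392819E-14    4    3    4    2
 7.6550481622192912E-02    4    3    4    3
 3.3881813078862416E-01    4    4    1    1
-8.9886431631214236E-14    4    4    2    1
 2.9308007929132718E-01    4    4    2    2
-4.7967819180213207E-02    4    4    3    1
-3.6984304507825527E-14    4    4    3    2
 2.9232118292410181E-01    4    4    3    3
 1.1591422266477025E-14    4    4    4    1
-4.6702304565926597E-02    4    4    4    2
-1.9137469386976136E-14    4    4    4    3
 3.2687876361035639E-01    4    4    4    4
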