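&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.5721756894318196E-01    1    1    1    1
-9.5349943218803190E-14    2    1    1    1
 1.1096590061780526E-01    2    1    2    1
 3.2141344512734005E-01    2    2    1    1
 9.0569912680749098E-14    2    2    2    1
 3.2599810795749196E-01    2    2    2    2
-4.6265221137578541E-02    3    1    1    1
-5.1876905549086416E-14    3    1    2    1
 3.9277010472956800E-03    3    1    2    2
 6.3489459381012692E-02    3    1    3    1
-8.2092319053650442E-14    3    2    1    1
 5.9646339213311791E-02    3    2    2    1
 2.8014049413549458E-14    3    2    2    2
-4.3926667858684709E-14    3    2    3    1
 8.3750613676913013E-02    3    2    3    2
 3.1239656495310952E-01    3    3    1    1
-5.6923216140702948E-14    3    3    2    1
 3.1049855680699345E-01    3    3    2    2
-2.5169786013201981E-03    3    3    3    1
-1.2052858711086856E-14    3    3    3    2
 3.0784227078880771E-01    3    3    3    3
-2.7661900547926166E-14    4    1    1    1
 2.3885515271358203E-02    4    1    2    1
 4.4025547096815387E-14    4    1    2    2
 5.8130149999113812E-14    4    1    3    1
-3.8519589519321579E-02    4    1    3    2
-3.7234104688366187E-14    4    1    3    3
 5.8580840439595772E-02    4    1    4    1
 4.6266565774638266E-02    4    2    1    1
 4.7159325056167489E-14    4    2    2    1
 4.8872294904012611E-03    4    2    2    2
-5.4527319067532040E-02    4    2    3    1
-5.4787771541775498E-14    4    2    3    2
 2.7565520159621160E-03    4    2    3    3
 4.8512409367429399E-14    4    2    4    1
 5.3040550320037301E-02    4    2    4    2
 1.2815443151126260E-13    4    3    1    1
-9.0304260973365177E-02    4    3    2    1
-7.8737363851111297E-14    4    3    2    2
-3.0277863549699191E-14    4    3    3    1
-5.0066203272120545E-02    4    3    3    2
 5.1863027761278602E-14    4    3    3    3
-2.1554792606966289E-02    4    3    4    1
 2.5094509803480491E-14    4    3    4    2
 8.3380005925648287E-02    4    3    4    3
 3.2958985823339859E-01    4    4    1    1
 1.0613732115416497E-13    4    4    2    1
 2.9908505051359857E-01    4    4    2    2
-4.1501144122787728E-02    4    4    3    1
 4.0460690353683049E-14    4    4    3    2
 2.9484438920422934E-01    4    4    3    3
 8.5556561835176126E-15    4    4    4    1
 4.2483378399754294E-02    4    4    4    2
-4.7076925691058591E-14    4    4    4    3
 3.1691435539395757E-01    4    4    4    4
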