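&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6421004388843836E-01    1    1    1    1
 6.3537716754602513E-14    2    1    1    1
 9.9619990041779002E-02    2    1    2    1
 3.1252915125803871E-01    2    2    1    1
-5.0192489053912936E-14    2    2    2    1
 3.2051107212830476E-01    2    2    2    2
-5.3625557948690464E-02    3    1    1    1
 7.3724013005538325E-14    3    1    2    1
 7.5402538796532064E-03    3    1    2    2
 6.3333348688611624E-02    3    1    3    1
 1.1323407489438608E-13    3    2    1    1
 6.4677479397871523E-02    3    2    2    1
 1.4998419173295474E-14    3    2    2    2
 4.1516269588814936E-14    3    2    3    1
 9.4332216530769467E-02    3    2    3    2
 3.0904609601836303E-01    3    3    1    1
 2.8393953854788379E-14    3    3    2    1
 3.0941271776597590E-01    3    3    2    2
 3.3356303357109235E-04    3    3    3    1
-2.6312285683616210E-14    3    3    3    2
 3.0899621389428156E-01    3    3    3    3
-2.6344378067921781E-14    4    1    1    1
-2.7573599942007029E-02    4    1    2    1
 7.5226283535734240E-14    4    1    2    2
 7.1788928968086196E-14    4    1    3    1
 3.4183085721580186E-02    4    1    3    2
-5.7143526022152002E-14    4    1    3    3
 6.2386795382295482E-02    4    1    4    1
-5.0260856349255548E-02    4    2    1    1
 9.3423532798730946E-14    4    2    2    1
-8.9284490737090091E-05    4    2    2    2
 5.3285224806179560E-02    4    2    3    1
-5.3183152326496952E-14    4    2    3    2
 1.0865084061939378E-03    4    2    3    3
-6.4395103832604050E-14    4    2    4    1
 5.1417163334169950E-02    4    2    4    2
 1.5856326668339804E-13    4    3    1    1
 8.2706411954461073E-02    4    3    2    1
-5.4396591397942728E-14    4    3    2    2
-6.4497018836817688E-14    4    3    3    1
 5.5038921325777736E-02    4    3    3    2
 2.4208066107256343E-14    4    3    3    3
-2.5587580201419310E-02    4    3    4    1
-2.9918775790171992E-14    4    3    4    2
 7.7613531235125321E-02    4    3    4    3
 3.3745079786309601E-01    4    4    1    1
-1.3813603039203315E-13    4    4    2    1
 2.9401486767046170E-01    4    4    2    2
-4.7121833886381997E-02    4    4    3    1
-4.8315518252906031E-14    4    4    3    2
 2.9281575617096078E-01    4    4    3    3
 1.2857770403940094E-14    4    4    4    1
-4.6187021057115342E-02    4    4    4    2
-2.6034729927459921E-14    4    4    4    3
 3.2550262197605007E-01    4    4    4    4
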