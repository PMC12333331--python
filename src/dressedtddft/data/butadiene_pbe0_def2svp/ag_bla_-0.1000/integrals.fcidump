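&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.7236563665704281E-01    1    1    1    1
 2.2523649612082863E-14    2    1    1    1
 9.0168641878561925E-02    2    1    2    1
 3.0511691886312636E-01    2    2    1    1
-1.4970663597679845E-14    2    2    2    1
 3.1724434451611455E-01    2    2    2    2
-5.9468030263493218E-02    3    1    1    1
 2.7386079515245854E-14    3    1    2    1
 1.0552311425205038E-02    3    1    2    2
 6.2187685066602182E-02    3    1    3    1
 4.5745959104115386E-14    3    2    1    1
 6.7961987158128817E-02    3    2    2    1
 3.6186331708876196E-15    3    2    2    2
 1.4929897595994390E-14    3    2    3    1
 1.0379652122201706E-01    3    2    3    2
 3.0545330868638987E-01    3    3    1    1
 9.5895513751997896E-15    3    3    2    1
 3.0892253208660142E-01    3    3    2    2
 2.9086347534909435E-03    3    3    3    1
-8.8679064091934379E-15    3    3    3    2
 3.0980428046079533E-01    3    3    3    3
-2.1524448889920222E-14    4    1    1    1
-3.0152234084461885E-02    4    1    2    1
 2.7017450776600782E-14    4    1    2    2
 2.9947832408394603E-14    4    1    3    1
 2.9647074256086755E-02    4    1    3    2
-1.9856512267768522E-14    4    1    3    3
 6.5711087902042789E-02    4    1    4    1
-5.3076735718930110E-02    4    2    1    1
 3.5981634338710933E-14    4    2    2    1
 3.8088924726258529E-03    4    2    2    2
 5.1235244017670781E-02    4    2    3    1
-1.7050597045376037E-14    4    2    3    2
 4.3808775058283593E-03    4    2    3    3
-2.2017110357097636E-14    4    2    4    1
 4.9087825144323971E-02    4    2    4    2
 6.2348563811820412E-14    4    3    1    1
 7.5690398857961874E-02    4    3    2    1
-1.7802599672211983E-14    4    3    2    2
-2.1224341728576235E-14    4    3    3    1
 5.8325980242447485E-02    4    3    3    2
 7.8374806644632145E-15    4    3    3    3
-2.8398394713967171E-02    4    3    4    1
-6.6231742312794495E-15    4    3    4    2
 7.1837163847038282E-02    4    3    4    3
 3.4472298608878627E-01    4    4    1    1
-4.6695286526343693E-14    4    4    2    1
 2.8891987698263322E-01    4    4    2    2
-5.1217012860160206E-02    4    4    3    1
-1.1858569681777453E-14    4    4    3    2
 2.8982285535151969E-01    4    4    3    3
 3.7608804959177178E-15    4    4    4    1
-4.8544054896378024E-02    4    4    4    2
-2.9629076969683865E-15    4    4    4    3
 3.3250295372874988E-01    4    4    4    4
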