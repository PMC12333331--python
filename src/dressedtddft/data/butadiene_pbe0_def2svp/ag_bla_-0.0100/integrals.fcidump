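&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6491147425302550E-01    1    1    1    1
-4.4825254619240695E-15    2    1    1    1
 9.8704064015656678E-02    2    1    2    1
 3.1181281339907496E-01    2    2    1    1
 4.7011006198971472E-15    2    2    2    1
 3.2014462508113017E-01    2    2    2    2
-5.4207424520315663E-02    3    1    1    1
-2.7885679876327174E-15    3    1    2    1
 7.8358010453349718E-03    3    1    2    2
 6.3262171003712495E-02    3    1    3    1
-5.4010615424537889E-15    3    2    1    1
 6.5035925588461663E-02    3    2    2    1
 3.2803620930721422E-15    3    2    2    2
 1.5733941927109640E-15    3    2    3    1
 9.5226482652447458E-02    3    2    3    2
 3.0872968191460898E-01    3    3    1    1
 3.6845526629747383E-15    3    3    2    1
 3.0934718265893835E-01    3    3    2    2
 5.7778724978847784E-04    3    3    3    1
 8.3266726846886741E-17    3    3    3    2
 3.0907775746659694E-01    3    3    3    3
-6.9397612656452168E-15    4    1    1    1
 2.7847047147854281E-02    4    1    2    1
 4.2847669856627135E-16    4    1    2    2
 3.3692666712159536E-15    4    1    3    1
-3.3776278688815289E-02    4    1    3    2
 2.7564756033271465E-15    4    1    3    3
 6.2703878815506042E-02    4    1    4    1
 5.0557650380903749E-02    4    2    1    1
 3.4547018024078113E-15    4    2    2    1
-2.9616740642463002E-04    4    2    2    2
-5.3124977991655137E-02    4    2    3    1
 2.2178439640363479E-15    4    2    3    2
-1.4055459074794087E-03    4    2    3    3
-5.9913012051548975E-15    4    2    4    1
 5.1227490126966327E-02    4    2    4    2
 4.9587070560797031E-15    4    3    1    1
-8.2050244036725034E-02    4    3    2    1
 3.5475095083725705E-16    4    3    2    2
 5.6673415960162288E-15    4    3    3    1
-5.5395142782473608E-02    4    3    3    2
 3.7990444123892075E-16    4    3    3    3
-2.5885792583766571E-02    4    3    4    1
-5.9119376061289586E-15    4    3    4    2
 7.7087862755155015E-02    4    3    4    3
 3.3812902606014561E-01    4    4    1    1
-1.0231399061311208E-14    4    4    2    1
 2.9355273130927018E-01    4    4    2    2
-4.7546051721149861E-02    4    4    3    1
-9.8324126618365426E-15    4    4    3    2
 2.9257483229361703E-01    4    4    3    3
-7.5286998857393428E-15    4    4    4    1
 4.6447020218548359E-02    4    4    4    2
 9.9573127521068727E-15    4    4    4    3
 3.2618899908018845E-01    4    4    4    4
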