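&FCI NORB=2,NELEC=30,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
&END
 3.2599810795749190E-01    1    1    1    1
 2.8010579966597504E-14    2    1    1    1
 8.3750613676913013E-02    2    1    2    1
 3.1049855680699345E-01    2    2    1    1
-1.2066736498894670E-14    2    2    2    1
 3.0784227078880771E-01    2    2    2    2
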