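&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6288030102307145E-01    1    1    1    1
 8.4044750325862339E-14    2    1    1    1
 1.0143254590993214E-01    2    1    2    1
 3.1394633089048318E-01    2    2    1    1
-7.2358785629944578E-14    2    2    2    1
 3.2126916076313639E-01    2    2    2    2
-5.2466427486549880E-02    3    1    1    1
 7.9579572098698037E-14    3    1    2    1
 6.9551500156360517E-03    3    1    2    2
 6.3448581440050111E-02    3    1    3    1
 1.2405788202274337E-13    3    2    1    1
 6.3944846455137788E-02    3    2    2    1
 6.9388939039072284E-16    3    2    2    2
 4.9070990326693931E-14    3    2    3    1
 9.2578680933978141E-02    3    2    3    2
 3.0965208724372706E-01    3    3    1    1
 4.1924796967407474E-14    3    3    2    1
 3.0955313023081832E-01    3    3    2    2
-1.4484962309999766E-04    3    3    3    1
-1.6285583992470265E-14    3    3    3    2
 3.0883125322895966E-01    3    3    3    3
-3.1209410056298736E-14    4    1    1    1
-2.7019618623078528E-02    4    1    2    1
 7.8896091049163175E-14    4    1    2    2
 7.7980157053847421E-14    4    1    3    1
 3.4965084148077009E-02    4    1    3    2
-5.9622445869322860E-14    4    1    3    3
 6.1763235280337288E-02    4    1    4    1
-4.9660282790387561E-02    4    2    1    1
 9.4273547301959582E-14    4    2    2    1
-8.5489547018344388E-04    4    2    2    2
 5.3576813867877174E-02    4    2    3    1
-6.4935036514501832E-14    4    2    3    2
 4.5722342334759795E-04    4    2    3    3
-7.2821089436292397E-14    4    2    4    1
 5.1768001929430374E-02    4    2    4    2
 1.7271774288563080E-13    4    3    1    1
 8.3987917242075161E-02    4    3    2    1
-7.4943523609150020E-14    4    3    2    2
-6.3518634796366769E-14    4    3    3    1
 5.4312004371912595E-02    4    3    3    2
 3.4822839056758426E-14    4    3    3    3
-2.4983210258650433E-02    4    3    4    1
-3.2720354203874535E-14    4    3    4    2
 7.8629618290711162E-02    4    3    4    3
 3.3612679368657417E-01    4    4    1    1
-1.5474080350408315E-13    4    4    2    1
 2.9490770015236190E-01    4    4    2    2
-4.6267173094762498E-02    4    4    3    1
-5.4331539267593598E-14    4    4    3    2
 2.9325986568100076E-01    4    4    3    3
 1.8707257964933888E-14    4    4    4    1
-4.5653860326789975E-02    4    4    4    2
-4.2552766865711078E-14    4    4    4    3
 3.2414039230129471E-01    4    4    4    4
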