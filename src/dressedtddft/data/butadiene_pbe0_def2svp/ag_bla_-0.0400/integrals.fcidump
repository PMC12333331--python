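&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.6716509390062091E-01    1    1    1    1
 1.6025809151942738E-13    2    1    1    1
 9.5917308408210653E-02    2    1    2    1
 3.0963157999419477E-01    2    2    1    1
-1.2354353651211625E-13    2    2    2    1
 3.1909705903715890E-01    2    2    2    2
-5.5959400296873033E-02    3    1    1    1
 1.9009880475318042E-13    3    1    2    1
 8.7323349064120457E-03    3    1    2    2
 6.2992533340957071E-02    3    1    3    1
 2.9846611293571357E-13    3    2    1    1
 6.6075620252441986E-02    3    2    2    1
 2.5129204273000028E-14    3    2    2    2
 1.0830485813739799E-13    3    2    3    1
 9.7979310264719538E-02    3    2    3    2
 3.0772497541424909E-01    3    3    1    1
 7.2535727424494212E-14    3    3    2    1
 3.0917097835019913E-01    3    3    2    2
 1.3294792730665361E-03    3    3    3    1
-6.7869321274116601E-14    3    3    3    2
 3.0932002146033288E-01    3    3    3    3
-9.9001536135734369E-14    4    1    1    1
-2.8649990408305275E-02    4    1    2    1
 1.8621215680525438E-13    4    1    2    2
 1.9415111879306224E-13    4    1    3    1
 3.2492841958155355E-02    4    1    3    2
-1.4983066870533079E-13    4    1    3    3
 6.3676140738299830E-02    4    1    4    1
-5.1431006594721607E-02    4    2    1    1
 2.3618433597771826E-13    4    2    2    1
 1.4608515309926153E-03    4    2    2    2
 5.2585379552376146E-02    4    2    3    1
-1.3935640835738283E-13    4    2    3    2
 2.3785121078469789E-03    4    2    3    3
-1.6389624032941974E-13    4    2    4    1
 5.0600972860554733E-02    4    2    4    2
 4.1765028935270010E-13    4    3    1    1
 8.0020423836569987E-02    4    3    2    1
-1.4298891931607827E-13    4    3    2    2
-1.6400943103622723E-13    4    3    3    1
 5.6431063975228922E-02    4    3    3    2
 5.6043711338382707E-14    4    3    3    3
-2.6761156752594641E-02    4    3    4    1
-7.6338241283835373E-14    4    3    4    2
 7.5440757116455634E-02    4    3    4    3
 3.4022907002139108E-01    4    4    1    1
-3.5269356879474856E-13    4    4    2    1
 2.9210316436103551E-01    4    4    2    2
-4.8802826584184625E-02    4    4    3    1
-1.2160411566597418E-13    4    4    3    2
 2.9177530171178739E-01    4    4    3    3
 2.9795610423377639E-14    4    4    4    1
-4.7197721909286894E-02    4    4    4    2
-5.6645660384546659E-14    4    4    4    3
 3.2826801237922609E-01    4    4    4    4
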