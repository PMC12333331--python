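&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.5849615313665217E-01    1    1    1    1
-7.0849576205844755E-14    2    1    1    1
 1.0843521948082943E-01    2    1    2    1
 3.1942638678371760E-01    2    2    1    1
 7.1460198869388591E-14    2    2    2    1
 3.2461949664455603E-01    2    2    2    2
-4.7920616448514454E-02    3    1    1    1
-3.8183865791463489E-14    3    1    2    1
 4.7164161074275748E-03    3    1    2    2
 6.3571371292653917E-02    3    1    3    1
-6.2294787384065131E-14    3    2    1    1
 6.0851907639273395E-02    3    2    2    1
 3.0113064819481394E-14    3    2    2    2
-2.6517850415519462E-14    3    2    3    1
 8.6024500176001439E-02    3    2    3    2
 3.1174070936462583E-01    3    3    1    1
-3.1710745140856034E-14    3    3    2    1
 3.1021763939311531E-01    3    3    2    2
-1.9152502501305832E-03    3    3    3    1
-5.9327542878406803E-15    3    3    3    2
 3.0812999572621924E-01    3    3    3    3
-2.8898758386297629E-14    4    1    1    1
 2.4745782598598134E-02    4    1    2    1
 2.9864132000678723E-14    4    1    2    2
 4.3648244740790432E-14    4    1    3    1
-3.7673758348904962E-02    4    1    3    2
-2.2948656863697181E-14    4    1    3    3
 5.9408701158703905E-02    4    1    4    1
 4.7198952485904812E-02    4    2    1    1
 3.4793348757666820E-14    4    2    2    1
 3.8229366238690925E-03    4    2    2    2
-5.4373072845933165E-02    4    2    3    1
-3.9405111118551162E-14    4    2    3    2
 1.9253379373800981E-03    4    2    3    3
 2.8638549864901108E-14    4    2    4    1
 5.2800516019925289E-02    4    2    4    2
 9.2735714940506142E-14    4    3    1    1
-8.8703303272113732E-02    4    3    2    1
-6.0609503527153663E-14    4    3    2    2
-1.4578616092109087E-14    4    3    3    1
-5.1254798766295719E-02    4    3    3    2
 3.0512051218956060E-14    4    3    3    3
-2.2497904245632534E-02    4    3    4    1
 1.0980799602933189E-14    4    3    4    2
 8.2223982014654251E-02    4    3    4    3
 3.3125204777138062E-01    4    4    1    1
 6.4011296263544182E-14    4    4    2    1
 2.9806637825210569E-01    4    4    2    2
-4.2802968461375226E-02    4    4    3    1
 1.8922363675955012E-14    4    4    3    2
 2.9455098815609077E-01    4    4    3    3
 1.8943180357666733E-15    4    4    4    1
 4.3379558091218531E-02    4    4    4    2
-2.4792667918660527E-14    4    4    4    3
 3.1883973965693002E-01    4    4    4    4
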