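9.251585526008627991e-02 -8.382295575586255765e-02
-8.382295575586255765e-02 7.399407381555363206e-02
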