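9.196990308534773451e-02 8.251494312768323236e-02
8.251494312768323236e-02 7.139215094098193271e-02
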