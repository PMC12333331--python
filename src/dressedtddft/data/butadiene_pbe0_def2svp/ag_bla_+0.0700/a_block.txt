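3.346997145474864266e-01 -7.137498137960092415e-02
-7.137498137960092415e-02 3.297277345377465640e-01
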