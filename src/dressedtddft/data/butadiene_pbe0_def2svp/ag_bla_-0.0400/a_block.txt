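3.197649944852928861e-01 7.101135030468117004e-02
7.101135030468117004e-02 3.149905599049465654e-01
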