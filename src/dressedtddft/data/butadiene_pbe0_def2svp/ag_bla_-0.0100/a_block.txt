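3.237345922854166225e-01 -7.128069376978134197e-02
-7.128069376978134197e-02 3.188596866632373850e-01
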