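3.305194537952694800e-01 -7.144212832234198007e-02
-7.144212832234198007e-02 3.255597288053422300e-01
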