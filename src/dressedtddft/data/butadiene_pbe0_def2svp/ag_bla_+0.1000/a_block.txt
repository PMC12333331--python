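3.389682910598721954e-01 -7.119171052707418124e-02
-7.119171052707418124e-02 3.340057703727112304e-01
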