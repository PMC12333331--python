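9.235535872126041101e-02 8.321186443507663788e-02
8.321186443507663788e-02 7.260567499823046556e-02
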