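9.251534532530528154e-02 8.367526915026587964e-02
8.367526915026587964e-02 7.358806208084263389e-02
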