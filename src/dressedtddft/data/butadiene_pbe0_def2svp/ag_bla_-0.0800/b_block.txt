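9.168777994889609761e-02 -8.207583096982970505e-02
-8.207583096982970505e-02 7.069793092495531284e-02
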