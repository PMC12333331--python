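3.120331486598283965e-01 7.006412441932111101e-02
7.006412441932111101e-02 3.076069298414468300e-01
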