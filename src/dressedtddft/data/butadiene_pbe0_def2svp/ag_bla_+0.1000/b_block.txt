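9.222436426737426474e-02 -8.394909675787638748e-02
-8.394909675787638748e-02 7.488222352916663882e-02
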