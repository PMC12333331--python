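9.219180214551636610e-02 8.289324577428480723e-02
8.289324577428480723e-02 7.202801346723898546e-02
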