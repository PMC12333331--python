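9.134365192245240406e-02 8.157495556978988649e-02
8.157495556978988649e-02 6.994543169833392082e-02
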