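9.246253310000165926e-02 8.347207266491649125e-02
8.347207266491649125e-02 7.312550488865625364e-02
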