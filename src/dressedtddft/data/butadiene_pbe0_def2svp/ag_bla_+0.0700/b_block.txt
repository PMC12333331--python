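9.242310324654236242e-02 -8.394388805665142783e-02
-8.394388805665142783e-02 7.449902116285420095e-02
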