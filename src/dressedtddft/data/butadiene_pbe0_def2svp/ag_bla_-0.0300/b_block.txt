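9.228075234019388062e-02 8.305993920215976045e-02
8.305993920215976045e-02 7.232410098899497153e-02
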