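3.250742074854220953e-01 7.134124110669629037e-02
7.134124110669629037e-02 3.201747766554532415e-01
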