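2.898399993414976783e-01
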