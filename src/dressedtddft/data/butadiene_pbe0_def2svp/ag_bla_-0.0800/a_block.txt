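3.145810666374549425e-01 -7.044164753608583851e-02
-7.044164753608583851e-02 3.100140960055796091e-01
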