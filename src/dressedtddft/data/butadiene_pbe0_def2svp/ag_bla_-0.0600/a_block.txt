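3.171579865916608343e-01 7.075706598711631323e-02
7.075706598711631323e-02 3.124757855109306925e-01
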