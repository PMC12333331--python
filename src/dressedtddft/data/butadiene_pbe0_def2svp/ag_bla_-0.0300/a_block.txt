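3.210801547872272899e-01 7.111591847379380993e-02
7.111591847379380993e-02 3.162674693311670060e-01
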