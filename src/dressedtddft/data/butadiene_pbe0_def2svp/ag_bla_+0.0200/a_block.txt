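3.277791091826939285e-01 7.141956087676636089e-02
7.141956087676636089e-02 3.228424712028215016e-01
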