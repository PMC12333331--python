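3.433304434947515027e-01 -7.089819369953431760e-02
-7.089819369953431760e-02 3.383939070457856468e-01
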