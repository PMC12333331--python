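9.192655845917691027e-02 -8.384436156304522769e-02
-8.384436156304522769e-02 7.514766649471364690e-02
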