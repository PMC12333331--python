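9.241586861431422273e-02 -8.334918510675876080e-02
-8.334918510675876080e-02 7.287278814103760605e-02
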