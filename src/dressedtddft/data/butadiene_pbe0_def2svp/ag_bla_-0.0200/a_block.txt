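3.224032985352578429e-01 7.120564424575612228e-02
7.120564424575612228e-02 3.175572167735413176e-01
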