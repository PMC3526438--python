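(a_1,((a_2,a_3),(b_2,b_3)));
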