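((((M1,Rt1),(Rb1,(H1,(P1,B1)))),(S4,B4)),(((M2,Rt2),H2),(M3,(H3p,H3pp))));
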