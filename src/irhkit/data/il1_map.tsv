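M1	Mouse
Rt1	Rat
Rb1	Rabbit
H1	Human
P1	Pig
B1	Bovine
M2	Mouse
Rt2	Rat
H2	Human
M3	Mouse
H3	Human
H3p	Human
H3pp	Human
S4	Sheep
B4	Bovine
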