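state	central	low	high
A	16340	13889	18790
B	8681	7378	9983
C	0	0	0
D	0	0	0
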