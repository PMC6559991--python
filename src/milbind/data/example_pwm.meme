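MEME version 4

ALPHABET= ACGT

strands: +

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF synthetic_example
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
 0.05 0.05 0.05 0.85
 0.05 0.05 0.85 0.05
 0.85 0.05 0.05 0.05
 0.05 0.85 0.05 0.05
 0.05 0.05 0.85 0.05
 0.05 0.05 0.05 0.85
 0.05 0.85 0.05 0.05
 0.85 0.05 0.05 0.05
 0.05 0.05 0.05 0.85
 0.05 0.05 0.85 0.05
 0.05 0.85 0.05 0.05
 0.85 0.05 0.05 0.05
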