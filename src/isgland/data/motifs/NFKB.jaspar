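>NFKB
A [  2  2  2 60 20 20  5  5  2  2 ]
C [  3  3  3  5 40 20 30 30 94 94 ]
G [ 93 93 93 30 20 20  5  5  2  2 ]
T [  2  2  2  5 20 40 60 60  2  2 ]
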