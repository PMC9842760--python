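>GAS
A [  2  2  2 20 20 20  2 95 95 ]
C [  2  2 94 40 20 20  2  1  1 ]
G [  1  1  2 20 40 40 95  2  2 ]
T [ 95 95  2 20 20 20  1  2  2 ]
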