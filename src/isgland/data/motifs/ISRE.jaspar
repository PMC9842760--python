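>ISRE
A [ 85  2  1  1  1  2 40 20  1  1  1  2 ]
C [  5  2  2  2  2 94 20 20  2  2  2 94 ]
G [  5 94  2  2  2  2 20 40  2  2  2  2 ]
T [  5  2 95 95 95  2 20 20 95 95 95  2 ]
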