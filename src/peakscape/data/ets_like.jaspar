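>ETS_like
A [ 80 5 80 5 5 85 85 5 5 ]
C [ 10 80 5 5 5 5 5 5 5 ]
G [ 5 5 10 85 85 5 5 80 10 ]
T [ 5 10 5 5 5 5 5 10 80 ]
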