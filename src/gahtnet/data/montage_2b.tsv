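C3	-2	0
Cz	0	0
C4	2	0
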