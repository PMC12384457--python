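Fz	0	2
FC3	-2	1
FC1	-1	1
FCz	0	1
FC2	1	1
FC4	2	1
C5	-3	0
C3	-2	0
C1	-1	0
Cz	0	0
C2	1	0
C4	2	0
C6	3	0
CP3	-2	-1
CP1	-1	-1
CPz	0	-1
CP2	1	-1
CP4	2	-1
P1	-1	-2
Pz	0	-2
P2	1	-2
POz	0	-3
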