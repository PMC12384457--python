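Fz,FC3
Fz,FC1
Fz,FCz
Fz,FC2
Fz,FC4
FC3,FC1
FC3,C5
FC3,C3
FC1,FCz
FC1,C3
FC1,C1
FCz,FC2
FCz,C1
FCz,Cz
FCz,C2
FC2,FC4
FC2,C2
FC2,C4
FC4,C4
FC4,C6
C5,C3
C5,CP3
C3,C1
C3,CP3
C3,CP1
C1,Cz
C1,CP1
C1,CPz
Cz,C2
Cz,CPz
C2,C4
C2,CPz
C2,CP2
C4,C6
C4,CP2
C4,CP4
C6,CP4
CP3,CP1
CP3,P1
CP1,CPz
CP1,P1
CP1,Pz
CPz,CP2
CPz,Pz
CP2,CP4
CP2,Pz
CP2,P2
CP4,P2
P1,Pz
P1,POz
Pz,P2
Pz,POz
P2,POz
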