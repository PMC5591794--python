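udise,PRINGLE,VOTE,NOHL,PTLTBE
N0,X,X,N1/N2,X
N1,X,X,N3,X
N2,X,X,N4,X
V0AP,G1,V0AP,OAP1/OAP2,P1
V1AP,G1,V1AP,OAP3,P2
V2AP,G2,V2AP,OAP4,P2
V0L,G1,V0L,OT1/OT2,-
V1L,G1,V1L,OT3,-
V2L,G2,V2L,OT4,-
V0C,G1,V0C,OC1/OC2,P1
V1C,G1,V1C,OC3,P3
V2C,G2,V2C,OC4,P3
Ts0L,G1,O0L,-,T1
Ts1L,G1,O1L,-,T2
Ts2L,G2,O2L,TS3/TS4,T3
O0AP,-,-,OT1/OT2,-
O1AP,-,-,OT3,-
O2AP,G3/G4,-,OT4,-
O0L,-,O0L,OT1/OT2,L1
O1L,-,O1L,OT3,L2
O2L,G3/G4,O2L,OT4,L3
O0C,-,-,OC1/OC2,-
O1C,-,-,OC3,-
O2C,G3/G4,-,OC4,-
Tb0AP,G5,T0AP,HAP1/HAP2,Tb1
Tb1AP,G5,T1AP,HAP3,Tb2
Tb2AP,G5,T2AP,HAP4,Tb3
Tb0L,G5,-,HT1/HT2,-
Tb1L,G5,-,HT3,-
Tb2L,G5,-,HT4,-
Tb0C,G5,-,HC1/HC2,-
Tb1C,G5,-,HC3,-
Tb2C,G5,-,HC4,-
E0AP,G5,E0AP,LN,E1
E1AP,G5,E1AP,LP,E2
E2AP,G5,E2AP,LP,E2
E0L,G5,E0L,LN,-
E1L,G5,E1L,LP,-
E2L,G5,E2L,LP,-
L0,X,X,LN,X
L1,X,X,LP,X
L2,X,X,LP,X
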