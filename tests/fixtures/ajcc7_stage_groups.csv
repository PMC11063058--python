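t,n,m,stage
T1a,N0,M0,IA
T1a,N1,M0,IIA
T1a,N2,M0,IIIA
T1a,N3,M0,IIIB
T1b,N0,M0,IA
T1b,N1,M0,IIA
T1b,N2,M0,IIIA
T1b,N3,M0,IIIB
T2a,N0,M0,IB
T2a,N1,M0,IIA
T2a,N2,M0,IIIA
T2a,N3,M0,IIIB
T2b,N0,M0,IIA
T2b,N1,M0,IIB
T2b,N2,M0,IIIA
T2b,N3,M0,IIIB
T3,N0,M0,IIB
T3,N1,M0,IIIA
T3,N2,M0,IIIA
T3,N3,M0,IIIB
T4,N0,M0,IIIA
T4,N1,M0,IIIA
T4,N2,M0,IIIB
T4,N3,M0,IIIB
T1a,N0,M1,IV
T1a,N1,M1,IV
T1a,N2,M1,IV
T1a,N3,M1,IV
T1b,N0,M1,IV
T1b,N1,M1,IV
T1b,N2,M1,IV
T1b,N3,M1,IV
T2a,N0,M1,IV
T2a,N1,M1,IV
T2a,N2,M1,IV
T2a,N3,M1,IV
T2b,N0,M1,IV
T2b,N1,M1,IV
T2b,N2,M1,IV
T2b,N3,M1,IV
T3,N0,M1,IV
T3,N1,M1,IV
T3,N2,M1,IV
T3,N3,M1,IV
T4,N0,M1,IV
T4,N1,M1,IV
T4,N2,M1,IV
T4,N3,M1,IV
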