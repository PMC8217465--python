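Patient,Sex/Age,Onset/Fre,Electrode,PET-MRI,FLAWS,HFOs,Overlapped,Removing,Outcome
1,M/23,17/d,SEEG,"LT,LPT,LMP","LT,LPT,LMP","LH,LPT","LH,LPT,LMP","LH, LPT",I
2,M/29,5/d,SEEG,"RT,RH","RT, RH","RH,RA","RH,RT","RT, RH,RBF",I
3,F/42,12/m,SEEG,RSP,RP,"RP, RIP",RP,RP,II
4,M/16,7/w,SEEG,RPT,Normal,"RPT,LH",RPT,RPT,II
5,M/13,5/d,SEEG,RCS,RCS,"RP, RCS",RCS,RCR(*),II
6,F/17,1/w,SEEG,"RT,RP","RF,RCR","RF,RCR","RF,RCR",RF,III
7,M/20,6/m,SEEG,"LF,LOF,LTP,LH","LF,LOF,LT,LO,RO","LF,LH,RA","LF,LOF,LH","LOF,LTP,LH",III
8,F/26,9/w,SEEG,"RF,RT,RI","RT,RI",RT,RTRI,RIO(*),III
9,M/26,13/d,SEEG,RF,RF,RF,RF,RF,II
10,F/33,13/d,Sub/depth,"LP,LI",LT,"LO,LT,U","LT,LI","LT,LI",III
11,M/20,3/w,Sub/depth,/,"RF,RCR","RF,RCR","RF,RCR",RF,III
12,F/26,5/w,SEEG,LF,/,LF,LF,LF,I
13,F/13,12/w,SEEG,LF,/,LF,LF,LF,I
14,F/41,19/m,SEEG,RF,/,"RF,RMCC",RF,"RF,RCR",II
15,M/16,15/d,SEEG,RF,/,RF(#),RF,RF,I
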