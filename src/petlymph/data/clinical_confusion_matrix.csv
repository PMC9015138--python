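automatic,T,T+NT,SK,HN,HT,RK,LK,LI,GI,G,BL,BF,NT+NT
T,182,7,9,5,5,1,5,0,13,2,1,7,3
T+NT,4,10,0,0,0,0,0,0,0,0,0,0,2
SK,15,2,277,0,2,4,0,1,6,0,1,1,0
HN,11,1,4,81,0,0,0,0,0,0,0,1,0
HT,1,0,0,0,24,0,0,0,0,0,0,0,0
RK,2,0,1,0,0,61,0,0,0,0,0,0,0
LK,6,1,1,0,0,0,60,0,0,0,0,1,0
LI,0,0,0,0,0,0,0,0,0,0,0,0,0
GI,3,0,3,0,0,1,2,0,17,1,0,0,1
G,0,0,0,0,0,0,0,0,1,0,0,0,0
BL,0,0,0,0,0,0,0,0,0,0,0,0,0
BF,1,0,0,0,0,0,0,0,0,0,0,2,0
NT+NT,0,0,0,0,0,0,0,0,0,0,0,0,0
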