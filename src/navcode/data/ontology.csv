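region_id,acronym,parent_id,group,volume_mm3
1,grey,,grey,
2,CTX,1,CTX,
3,HPF,1,HPF,
4,TH,1,TH,
10,VIS,2,VIS,
11,VISp,10,VIS,3.8
12,VISpm,10,VIS,0.9
13,VISam,10,VIS,0.7
14,VISal,10,VIS,0.6
15,VISl,10,VIS,0.8
16,VISpor,10,VIS,0.5
20,RSP,2,RSP,
21,RSPv,20,RSP,2.1
22,RSPd,20,RSP,1.9
23,RSPagl,20,RSP,1.0
30,MO,2,MO,
31,MOs,30,MO,4.2
32,MOp,30,MO,3.9
40,SS,2,SS,
41,SSp,40,SS,6.1
42,SSs,40,SS,2.2
50,ACA,2,ACA,
51,ACAd,50,ACA,1.3
52,ACAv,50,ACA,0.9
60,ORB,2,ORB,
61,ORBvl,60,ORB,0.8
62,ORBm,60,ORB,0.6
70,AUD,2,AUD,
71,AUDd,70,AUD,0.7
72,AUDp,70,AUD,1.0
80,PTLp,2,PTLp,
81,VISa,80,PTLp,0.8
82,VISrl,80,PTLp,0.6
100,RHP,3,RHP,
101,SUB,100,RHP,1.1
102,ENT,100,RHP,3.2
103,POST,100,RHP,0.5
104,PRE,100,RHP,0.4
105,PAR,100,RHP,0.3
106,APr,100,RHP,0.2
107,HATA,100,RHP,0.1
110,HIP,3,HIP,
111,CA1,110,HIP,2.8
112,CA3,110,HIP,1.6
113,DG,110,HIP,1.9
200,ATN,4,ATN,
201,AM,200,ATN,0.4
202,AV,200,ATN,0.5
203,AD,200,ATN,0.2
204,LD,200,ATN,0.6
210,LP,4,TH,1.2
211,LGd,4,TH,0.9
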