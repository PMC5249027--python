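item_id,factor,mean_printed,sd_printed,majority_votes,replaced
1,SAT,0.91,0.05,20,0
2,SOC,0.64,0.18,14,0
3,SAT,0.68,0.16,15,0
4,SAT,0.59,0.21,13,0
5,SAT,0.73,0.14,16,0
6,FoS,0.68,0.16,15,0
7,FoS,0.86,0.07,19,0
8,SOC,0.45,0.28,10,0
9,OUT,0.77,0.12,17,0
10,OUT,0.68,0.16,15,0
11,OUT,0.91,0.05,20,0
12,MOB,0.45,0.28,10,0
13,SOC,0.95,0.03,21,0
14,SOC,0.91,0.05,20,0
15,SOC,0.77,0.12,17,0
16,SOC,0.82,0.09,18,0
17,SOC,0.59,0.21,13,0
18,SOC,0.77,0.12,17,0
19,SOC,0.68,0.16,15,0
20,SOC,0.64,0.18,14,0
21,SOC,0.77,0.12,17,0
22,SOC,0.86,0.07,19,0
23,SUP,0.45,0.28,10,0
24,SUP,0.59,0.21,13,0
25,SOC,0.77,0.12,17,0
26,FoS,0.91,0.05,20,0
27,FoS,0.82,0.09,18,0
28,FoS,0.73,0.14,16,0
29,OUT,0.82,0.09,18,0
30,BSI,0.50,0.25,11,0
31,SAT,0.55,0.23,12,0
32,SUP,0.45,0.28,10,0
33,SUP,0.45,0.28,10,0
34,MOB,0.77,0.12,17,0
35,MOB,0.68,0.16,15,0
36,MOB,0.68,0.16,15,0
37,MOB,0.77,0.12,17,0
38,MOB,0.41,0.30,9,0
39,MOB,0.73,0.14,16,0
40,FoS,0.86,0.08,19,0
41,MOB,0.55,0.23,12,0
42,FoS,0.59,0.21,13,0
43,MOB,0.59,0.21,13,0
44,MOB,0.77,0.12,17,0
45,MOB,0.50,0.25,11,0
46,MOB,0.73,0.14,16,0
47,FoS,0.72,0.15,22,1
48,SAT,0.55,0.23,12,0
49,SAT,0.68,0.16,15,0
50,SAT,0.59,0.21,13,0
51,MOB,0.55,0.23,12,0
52,FoS,0.55,0.23,12,0
53,MOB,0.59,0.21,13,0
54,SUP,0.55,0.23,12,0
55,SAT,0.45,0.28,10,0
56,BSI,0.77,0.12,17,0
57,BSI,0.91,0.05,20,0
58,BSI,0.82,0.09,18,0
59,BSI,0.86,0.07,19,0
60,BSI,0.86,0.07,19,0
61,BSI,0.86,0.07,19,0
62,BSI,0.73,0.14,16,0
63,BSI,0.64,0.18,14,0
64,FoS,0.55,0.23,12,0
65,BSI,0.91,0.05,20,0
66,FoS,0.59,0.21,13,0
67,BSI,0.59,0.21,13,0
68,SOC,0.82,0.09,18,0
69,SAT,0.41,0.30,9,0
70,SAT,0.64,0.18,14,0
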