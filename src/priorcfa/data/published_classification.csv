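item_id,factor
1,SAT
2,SOC
3,SAT
4,SAT
5,SAT
6,FoS
7,FoS
8,SOC
9,OUT
10,OUT
11,OUT
12,MOB
13,SOC
14,SOC
15,SOC
16,SOC
17,SOC
18,SOC
19,SOC
20,SOC
21,SOC
22,SOC
23,SUP
24,SUP
25,SOC
26,FoS
27,FoS
28,FoS
29,OUT
30,BSI
31,SAT
32,SUP
33,SUP
34,MOB
35,MOB
36,MOB
37,MOB
38,MOB
39,MOB
40,FoS
41,MOB
42,FoS
43,MOB
44,MOB
45,MOB
46,MOB
47,FoS
48,SAT
49,SAT
50,SAT
51,MOB
52,FoS
53,MOB
54,SUP
55,SAT
56,BSI
57,BSI
58,BSI
59,BSI
60,BSI
61,BSI
62,BSI
63,BSI
64,FoS
65,BSI
66,FoS
67,BSI
68,SOC
69,SAT
70,SAT
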