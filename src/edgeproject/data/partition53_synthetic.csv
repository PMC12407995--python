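component_id,network
1,SC
2,SC
3,SC
4,SC
5,SC
6,AUD
7,AUD
8,SM
9,SM
10,SM
11,SM
12,SM
13,SM
14,SM
15,SM
16,SM
17,VIS
18,VIS
19,VIS
20,VIS
21,VIS
22,VIS
23,VIS
24,VIS
25,VIS
26,CC
27,CC
28,CC
29,CC
30,CC
31,CC
32,CC
33,CC
34,CC
35,CC
36,CC
37,CC
38,CC
39,CC
40,CC
41,CC
42,CC
43,DM
44,DM
45,DM
46,DM
47,DM
48,DM
49,DM
50,CB
51,CB
52,CB
53,CB
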