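image_id,obs1,obs2,auto,stratum
1,9,9,11,<10
2,8,6,8,<10
3,6,2,4,<10
4,5,3,6,<10
5,9,6,10,<10
6,5,4,7,<10
7,13,8,9,10-25
8,10,10,7,10-25
9,10,8,12,10-25
10,10,9,9,10-25
11,13,12,16,10-25
12,22,21,19,10-25
13,21,19,19,10-25
14,23,23,23,10-25
15,23,21,23,10-25
16,23,29,27,10-25
17,22,20,18,10-25
18,22,25,17,10-25
19,14,14,13,10-25
20,19,16,19,10-25
21,16,10,17,10-25
22,24,19,22,10-25
23,21,21,22,10-25
24,19,19,19,10-25
25,20,21,19,10-25
26,38,30,40,>25-40
27,30,31,34,>25-40
28,27,26,23,>25-40
29,40,33,42,>25-40
30,27,28,29,>25-40
31,29,25,33,>25-40
32,34,26,32,>25-40
33,36,30,35,>25-40
34,35,42,32,>25-40
35,34,40,36,>25-40
36,31,31,28,>25-40
37,31,30,28,>25-40
38,36,47,32,>25-40
39,35,39,34,>25-40
40,29,27,28,>25-40
41,47,36,48,>40
42,42,37,45,>40
43,46,35,50,>40
44,46,48,50,>40
45,41,29,38,>40
46,50,33,46,>40
47,41,33,45,>40
48,52,35,52,>40
49,42,33,44,>40
50,51,42,49,>40
51,43,37,42,>40
52,53,34,49,>40
53,51,34,52,>40
54,51,41,51,>40
55,45,41,44,>40
56,58,56,61,>40
57,58,64,54,>40
58,70,56,67,>40
59,68,65,65,>40
60,59,51,58,>40
61,62,48,58,>40
62,56,42,55,>40
63,56,56,57,>40
64,79,73,79,>40
65,56,45,57,>40
66,65,63,66,>40
67,62,50,64,>40
68,56,48,58,>40
69,60,54,54,>40
70,74,63,75,>40
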