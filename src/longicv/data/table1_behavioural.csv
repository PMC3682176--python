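subject_id,viq_t1,piq_t1,viq_t2,piq_t2,d_viq,d_piq
1,115,110,95,97,-20,-13
2,109,112,95,98,-14,-14
3,136,112,123,114,-13,2
4,115,110,104,111,-11,1
5,127,116,119,98,-8,-18
6,102,94,96,109,-6,15
7,108,109,104,106,-4,-3
8,133,101,130,114,-3,13
9,128,137,125,124,-3,-13
10,98,112,95,102,-3,-10
11,92,96,90,104,-2,8
12,96,116,94,110,-2,-6
13,100,90,100,95,0,5
14,117,125,117,113,0,-12
15,91,97,91,95,0,-2
16,102,119,102,102,0,-17
17,120,97,121,114,1,17
18,127,115,131,111,4,-4
19,137,105,142,107,5,2
20,108,110,113,107,5,-3
21,121,109,128,110,7,1
22,84,74,91,83,7,9
23,98,97,106,100,8,3
24,101,88,110,104,9,16
25,139,115,150,124,11,9
26,131,112,142,114,11,2
27,117,121,128,116,11,-5
28,129,118,144,117,15,-1
29,113,124,130,113,17,-11
30,91,105,108,105,17,0
31,120,103,138,85,18,-18
32,104,101,127,104,23,3
33,110,103,133,117,23,14
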