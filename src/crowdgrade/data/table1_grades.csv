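image_id,grade_2cat,consensus_2cat,grade_3cat,consensus_3cat,grade_4cat,consensus_4cat
1,0,0,0,0,0,0
2,1,1,1,2,1,3
3,0,0,0,0,0,0
4,0,1,0,1,0,0
5,0,0,0,0,0,0
6,1,1,1,1,1,2
7,1,1,2,2,3,2
8,0,1,0,1,0,0
9,1,1,2,2,3,3
10,1,1,2,1,3,3
11,1,1,2,1,3,1
12,0,0,0,0,0,0
13,1,1,1,2,2,3
14,1,1,2,1,3,2
15,0,0,0,0,0,0
16,1,1,2,2,3,3
17,1,1,1,1,1,2
18,1,1,1,1,2,2
19,1,1,1,1,1,2
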