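age,sex,n_screened,n_positive
7,male,3093,6
7,female,3128,8
8,male,2831,5
8,female,2970,5
9,male,3025,9
9,female,3540,13
10,male,3283,20
10,female,3432,28
11,male,3697,20
11,female,3834,34
12,male,3196,40
12,female,3294,74
13,male,3077,48
13,female,3234,82
14,male,3152,47
14,female,3352,84
15,male,2955,43
15,female,3011,65
16,male,3178,46
16,female,3525,82
17,male,3531,40
17,female,3570,51
18,male,3371,19
18,female,3574,28
19,male,2726,14
19,female,2881,18
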