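canonical_run_id,printed_run_id
1,3
2,11
3,13
4,6
5,8
6,10
7,14
8,4
9,1
10,9
11,12
12,5
13,2
14,7
15,15
16,16
17,17
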