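arm2	0	1	2	3	4	5
0	5	3	1	0	0	0
1	6	4	1	0	1	0
2	6	2	1	0	0	1
3	1	1	0	0	0	0
4	1	0	0	0	0	0
5	0	0	0	0	0	0
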