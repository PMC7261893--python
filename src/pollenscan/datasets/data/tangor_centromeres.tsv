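lg	cm
1	60.66
2	56.87
3	90.59
4	16.14
5	23.12
6	6.20
7	96.43
8	54.21
9	52.16
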