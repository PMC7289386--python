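n_nodes	n_components
1	188
2	62
3	13
4	18
5	6
6	4
8	2
9	1
10	1
11	1
12	1
13	1
15	1
17	1
18	1
23	1
464	1
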