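chromosome	sex	length_cM
1	F	98.1
1	M	88.3
2	F	95.1
2	M	85.7
3	F	92.1
3	M	83.0
4	F	89.1
4	M	80.3
5	F	86.2
5	M	77.7
6	F	83.2
6	M	75.0
7	F	80.2
7	M	72.3
8	F	77.3
8	M	69.6
9	F	74.3
9	M	66.9
10	F	71.3
10	M	64.3
11	F	68.3
11	M	61.6
12	F	65.4
12	M	58.9
13	F	62.4
13	M	56.2
14	F	59.4
14	M	53.6
15	F	56.5
15	M	50.9
16	F	53.5
16	M	48.2
17	F	50.5
17	M	45.5
18	F	47.5
18	M	42.8
19	F	44.6
19	M	40.2
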