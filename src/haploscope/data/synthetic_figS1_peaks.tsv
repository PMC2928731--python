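position	strand	A	C	G	T
1	F	0.98	0.02	0.01	0.02
1	R	1.02	0.01	0.02	0.01
2	F	0.02	0.01	1.01	0.02
2	R	0.01	0.02	0.97	0.01
3	F	0.01	0.99	0.02	0.03
3	R	0.02	1.03	0.01	0.02
4	F	0.02	0.64	0.01	0.36
4	R	0.01	0.67	0.02	0.33
5	F	1.03	0.02	0.01	0.02
5	R	0.99	0.01	0.03	0.02
6	F	0.02	0.01	0.98	0.01
6	R	0.01	0.02	1.01	0.02
7	F	0.01	0.35	0.02	0.63
7	R	0.02	0.37	0.01	0.66
8	F	0.02	1.02	0.01	0.02
8	R	0.01	0.98	0.02	0.01
9	F	0.99	0.01	0.02	0.02
9	R	1.01	0.02	0.01	0.03
10	F	0.02	0.33	0.01	0.65
10	R	0.01	0.36	0.02	0.68
11	F	0.01	0.02	1.02	0.01
11	R	0.02	0.01	0.99	0.02
12	F	0.02	0.01	0.02	1.01
12	R	0.01	0.02	0.01	0.97
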