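core_allele	activity_value	function_class
1	1.0	normal
2	1.0	normal
4	0	none
5	0	none
10	0.25	decreased
17	0.5	decreased
29	0.5	decreased
35	1.0	normal
36	0	none
40	0	none
41	0.5	decreased
45	1.0	normal
100	0	none
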