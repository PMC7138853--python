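channel_126	channel_127N	channel_127C	channel_128N	channel_128C	channel_129N	channel_129C	channel_130N	channel_130C	channel_131
0	0	0	0	0	0	1	1	0	0
0	0	0	0	0	0	1	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	1	0
0	0	1	1	0	0	0	0	0	0
0	0	0	0	0	1	0	0	1	0
1	0	0	1	1	0	1	1	0	0
0	0	0	0	0	1	1	1	0	0
1	0	0	0	0	0	0	0	0	0
1	0	1	1	0	0	1	0	1	0
0	0	0	0	0	0	0	0	0	0
1	0	1	1	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	0	0	0	0	0
0	0	0	0	0	1	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	1	0
1	0	1	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
1	0	0	0	0	0	1	0	1	0
0	0	0	0	0	0	1	0	1	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	0	1	0	0	0
1	0	0	0	0	0	0	0	0	0
1	0	0	0	1	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	1	0	0
0	0	0	0	0	0	0	0	0	0
0	0	1	0	0	0	0	0	0	0
0	0	0	1	0	0	0	0	0	0
0	1	0	0	0	0	0	0	0	0
0	1	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	1	0	1	0	0	0	0	1	0
0	0	0	0	0	0	0	0	0	0
0	0	0	1	0	1	0	0	0	0
0	0	0	0	0	0	0	1	0	0
0	0	1	0	0	0	0	0	0	0
0	0	0	1	0	1	0	0	0	0
0	0	0	0	0	1	0	0	1	0
0	0	0	0	0	0	1	0	0	0
1	1	0	1	0	0	0	0	0	0
0	1	0	0	0	0	0	0	0	0
0	0	0	0	0	1	0	0	0	0
1	1	1	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	1	0	1	0	0
0	0	0	0	1	0	0	1	0	0
0	0	0	0	1	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	1	0	0	0	0
0	0	1	0	1	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	0	0	0	1	0
1	0	0	0	0	0	0	1	0	0
0	0	0	1	0	0	0	0	1	0
0	0	1	0	0	0	1	0	0	0
1	1	0	0	0	0	1	1	0	0
0	1	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
1	0	0	0	0	1	0	0	0	0
1	0	0	0	0	0	0	0	0	0
0	0	0	0	0	1	0	0	0	0
0	0	0	0	1	0	0	0	0	0
0	0	0	0	0	0	1	0	0	0
0	0	0	1	1	0	0	0	1	0
0	0	0	0	0	0	0	0	0	0
1	0	0	0	0	1	0	0	0	0
0	1	0	1	0	0	0	0	1	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	1	0	0	0
0	0	0	1	0	0	0	0	0	0
0	0	1	0	0	0	0	1	0	0
0	0	0	0	0	0	0	0	0	0
1	0	1	0	0	0	0	1	0	0
0	0	0	0	0	1	0	0	0	0
0	1	0	1	0	0	0	0	0	0
0	0	1	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
1	0	0	1	0	0	1	1	0	0
0	0	0	0	0	0	0	0	0	0
0	1	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
1	0	0	0	0	0	0	0	0	0
0	0	0	0	0	1	0	0	0	0
0	0	0	1	0	0	0	1	0	0
0	0	0	0	0	0	1	0	0	0
0	0	0	0	0	0	0	0	0	0
1	0	0	0	1	0	0	0	1	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
0	0	1	1	1	0	0	0	0	0
0	0	0	0	0	0	0	0	0	0
1	0	0	0	0	0	0	1	0	0
1	0	0	0	0	0	0	0	0	0
0	0	0	1	1	0	1	0	0	0
1	0	0	0	0	0	0	0	0	0
0	0	0	0	0	1	0	0	1	0
0	0	0	0	0	0	0	0	0	0
0	0	0	0	1	0	1	0	0	0
0	0	0	0	0	0	0	0	1	0
0	0	0	0	0	0	0	0	0	0
0	0	1	0	0	0	0	0	0	0
1	0	1	0	0	0	1	1	0	0
0	0	0	0	0	0	0	0	0	0
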