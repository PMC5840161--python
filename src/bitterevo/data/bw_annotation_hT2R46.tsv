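# 1-based positions in the ungapped hT2R46 sequence -> BW / loop labels
66	2.61
70	2.65
71	2.66
82	3.25
85	3.29
88	3.32
89	3.33
92	3.36
93	3.37
150	4.65
161	ECL2
176	5.39
177	5.40
179	5.42
180	5.43
241	6.51
253	6.63
265	7.39
268	7.42
269	7.43
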