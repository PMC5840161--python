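# 1-based positions in the ungapped hT2R10 sequence -> BW / loop labels
65	2.61
69	2.65
70	2.66
81	3.25
85	3.29
88	3.32
89	3.33
92	3.36
93	3.37
150	4.65
159	ECL2
174	5.39
175	5.40
177	5.42
178	5.43
239	6.51
251	6.63
263	7.39
266	7.42
267	7.43
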