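pdb_id	tp	tn	fp	fn
1CD9	1	2	0	0
1HP7	5	3	0	1
1B10	2	2	0	1
1FC1	2	1	0	0
1EXZ	2	1	0	0
1QFK	2	1	1	0
1HGU	1	2	0	0
1Z7C	2	1	1	1
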