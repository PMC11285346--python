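# spliceindex v0.1.0 cell_type=T00 top=5 min_f1=0.2
node	gene	direction	tp	fp	fn	precision	recall	f1
G000_4	G000	inclusion	4	0	0	1	1	1
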