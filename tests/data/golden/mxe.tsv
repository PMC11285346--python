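# spliceindex v0.1.0 alpha=0.05 min_fraction=0.5 min_delta=0.5
gene	node_a	node_b	orientation	cell_type	p_value	fraction	delta_psi	adjacent	high_confidence
G001	G001_3	G001_4	a_in_b_out	T01	0.000549451	1	0.794925	True	True
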