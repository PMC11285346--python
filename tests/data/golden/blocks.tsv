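# spliceindex v0.1.0 alpha=0.05 min_exons=3 min_fraction=0.5
gene	node_range	n_nodes	n_exons	direction	cell_type	p_value	fraction	high_confidence
G002	2-4	3	3	above	T02	0.000549451	1	True
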