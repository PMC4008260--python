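# Default PME conserved-residue panel (tomato PME structural numbering).
ref_pos	ref_aa	class
80	F	AROMATIC_BINDING
109	Q	STABILIZER
131	Q	STABILIZER
132	D	CATALYTIC
135	Y	AROMATIC_BINDING
153	D	CATALYTIC
156	F	AROMATIC_BINDING
218	Y	AROMATIC_BINDING
221	R	CATALYTIC
223	W	AROMATIC_BINDING
248	W	AROMATIC_BINDING
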