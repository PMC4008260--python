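# Default PMEI conserved-residue panel (kiwi PMEI mature-protein numbering).
ref_pos	ref_aa	class
5	I	HYDROPHOBIC_BUNDLE
8	I	HYDROPHOBIC_BUNDLE
9	C	CYSTEINE
17	L	HYDROPHOBIC_BUNDLE
18	C	CYSTEINE
21	A	HYDROPHOBIC_BUNDLE
22	L	HYDROPHOBIC_BUNDLE
31	K	ORIENTATION
33	L	HYDROPHOBIC_BUNDLE
36	L	HYDROPHOBIC_BUNDLE
73	T	POLAR_INTERACTOR
74	C	CYSTEINE
76	E	POLAR_INTERACTOR
77	N	POLAR_INTERACTOR
80	D	ACIDIC_PATCH
83	D	ACIDIC_PATCH
96	D	ACIDIC_PATCH
109	D	ACIDIC_PATCH
113	T	POLAR_INTERACTOR
114	C	CYSTEINE
116	D	POLAR_INTERACTOR
138	L	HYDROPHOBIC_BUNDLE
141	I	HYDROPHOBIC_BUNDLE
144	V	HYDROPHOBIC_BUNDLE
145	I	HYDROPHOBIC_BUNDLE
148	L	HYDROPHOBIC_BUNDLE
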