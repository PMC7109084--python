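isotype	structure	res_a	resname_a	res_b	resname_b
CD1a	4X6E	77	SER	151	ASN
CD1b	5WKE	77	PHE	151	TYR
CD1c_1	6C15	77	LEU	152	TYR
CD1c_2	5C9J	80	ASP	155	TYR
CD1d	1ZT4	77	PHE	151	ASP
CD1e	3S6C	73	PHE	144	TYR
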