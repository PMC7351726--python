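compound_id	n_hbonds	residues
1	3	Asp133,Val135
3	1	Val135
4	1	Val135
2	4	Ile62,Asp133,Val135
6a	3	Ile62,Val135,Gln185
6b	1	Ile62
6c	4	Ile62,Val135,Asn186,Cys199
6f	3	Val135,Thr138
6i	3	Asn64,Tyr134,Gln185
6n	3	Ile62,Val135,Cys199
CHIR-98014	5	Ile62,Thr138,Val135,Gln185
Bio-acetoxime	3	Asp133,Val135
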