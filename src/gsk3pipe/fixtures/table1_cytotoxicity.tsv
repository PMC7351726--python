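compound_id	cell_line	ic50_uM	sd_uM	censored
1	HepG2	20		true
1	LU-1	20		true
1	SW480	20		true
1	HL-60	20		true
1	HEK-293	20		true
3	HepG2	20		true
3	LU-1	20		true
3	SW480	20		true
3	HL-60	20		true
3	HEK-293	20		true
4	HepG2	20		true
4	LU-1	19.55	1.23	false
4	SW480	18.59	0.91	false
4	HL-60	15.27	0.35	false
4	HEK-293	16.22	0.33	false
2	HepG2	16.0	0.62	false
2	LU-1	16.36	1.05	false
2	SW480	15.65	0.74	false
2	HL-60	16.5	0.94	false
2	HEK-293	14.16	0.71	false
6a	HepG2	3.56	0.75	false
6a	LU-1	2.26	0.32	false
6a	SW480	3.36	0.64	false
6a	HL-60	2.39	0.46	false
6a	HEK-293	3.21	0.43	false
6b	HepG2	20		true
6b	LU-1	20		true
6b	SW480	20		true
6b	HL-60	20		true
6b	HEK-293	20		true
6c	HepG2	3.38	0.68	false
6c	LU-1	2.99	0.55	false
6c	SW480	3.8	0.52	false
6c	HL-60	1.43	0.22	false
6c	HEK-293	1.19	0.12	false
6d	HepG2	3.76	0.75	false
6d	LU-1	2.85	0.74	false
6d	SW480	4.46	1.18	false
6d	HL-60	3.4	0.76	false
6d	HEK-293	2.01	0.64	false
6e	HepG2	4.62	1.07	false
6e	LU-1	3.28	0.48	false
6e	SW480	4.66	0.92	false
6e	HL-60	3.27	0.37	false
6e	HEK-293	6.98	0.25	false
6f	HepG2	2.01	0.43	false
6f	LU-1	1.3	0.14	false
6f	SW480	2.54	0.25	false
6f	HL-60	0.98	0.12	false
6f	HEK-293	1.03	0.11	false
6g	HepG2	5.68	0.71	false
6g	LU-1	3.96	0.62	false
6g	SW480	4.1	0.57	false
6g	HL-60	4.82	0.46	false
6g	HEK-293	1.8	0.21	false
6h	HepG2	14.23	1.79	false
6h	LU-1	8.74	0.55	false
6h	SW480	14.13	1.18	false
6h	HL-60	6.5	0.98	false
6h	HEK-293	9.74	0.53	false
6i	HepG2	2.28	0.12	false
6i	LU-1	2.07	0.26	false
6i	SW480	3.43	0.84	false
6i	HL-60	1.28	0.34	false
6i	HEK-293	0.85	0.05	false
6k	HepG2	2.95	0.19	false
6k	LU-1	2.5	0.34	false
6k	SW480	2.91	0.13	false
6k	HL-60	1.29	0.14	false
6k	HEK-293	1.92	0.17	false
6l	HepG2	3.28	0.25	false
6l	LU-1	2.07	0.31	false
6l	SW480	3.03	0.11	false
6l	HL-60	1.28	0.16	false
6l	HEK-293	7.12	0.18	false
6m	HepG2	15.31	0.17	false
6m	LU-1	8.74	1.06	false
6m	SW480	14.36	0.72	false
6m	HL-60	15.96	0.38	false
6m	HEK-293	11.93	1.75	false
6n	HepG2	11.7	0.23	false
6n	LU-1	10.08	0.44	false
6n	SW480	12.54	0.53	false
6n	HL-60	10.44	0.84	false
6n	HEK-293	9.52	0.07	false
6o	HepG2	11.68	0.26	false
6o	LU-1	8.8	0.38	false
6o	SW480	11.16	0.76	false
6o	HL-60	9.39	0.45	false
6o	HEK-293	5.89	0.75	false
6p	HepG2	10.61	0.79	false
6p	LU-1	8.61	0.57	false
6p	SW480	11.71	0.48	false
6p	HL-60	11.25	1.04	false
6p	HEK-293	7.72	0.42	false
Ellipticine	HepG2	1.93	0.54	false
Ellipticine	LU-1	2.5	0.82	false
Ellipticine	SW480	1.76	0.63	false
Ellipticine	HL-60	2.19	1.12	false
Ellipticine	HEK-293	0.32	0.03	false
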