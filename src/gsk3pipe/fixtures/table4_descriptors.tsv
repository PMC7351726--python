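compound_id	milogp	tpsa_A2	mw_g_mol	ld50_mg_kg	tox_class
1	2.9	65.72	262.27	1000	4
2	3.29	81.25	277.28	1000	4
3	3.13	54.87	300.32	1000	4
4	3.52	70.39	315.33	1000	4
6a	6.58	147.64	624.66	1000	4
6b	6.21	157.34	714.74	1000	4
6c	6.41	156.87	654.68	1000	4
6d	6.62	156.87	654.68	1000	4
6e	6.64	156.87	654.68	1000	4
6f	6.79	156.87	668.71	1000	4
6g	6.99	156.87	668.71	1000	4
6h	7.01	156.87	668.71	1000	4
6i	7.29	156.87	682.74	1000	4
6k	7.49	156.87	682.74	1000	4
6l	7.52	156.87	682.74	1000	4
6m	3.14	104.34	429.48	1000	4
6n	4.05	104.34	469.55	1000	4
6o	2.79	118.93	452.48	1000	4
6p	2.99	113.58	471.52	1000	4
Ellipticine	4.28	28.68	246.31	178	3
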