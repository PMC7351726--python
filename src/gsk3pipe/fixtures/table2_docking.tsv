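compound_id	dg_dock_kcal	ki_pred_M
1	-9.08	222.71E-09
2	-9.51	107.82E-09
3	-8.49	600.31E-09
4	-9.30	151.80E-09
6a	-13.64	99.73E-12
6b	-9.34	1.39E-06
6c	-13.17	222.30E-12
6d	-11.82	2.18E-09
6e	-13.18	219.20E-12
6f	-14.09	46.6E-12
6g	-13.72	87.29E-12
6h	-11.53	3.53E-09
6i	-12.85	380.41E-12
6k	-12.73	467.69E-12
6l	-13.78	79.11E-12
6m	-9.88	57.51E-09
6n	-11.55	3.43E-09
6o	-11.19	6.27E-09
6p	-11.25	5.71E-09
CHIR-98014	-11.82	2.18E-09
Bio-acetoxime	-10.69	14.06E-09
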