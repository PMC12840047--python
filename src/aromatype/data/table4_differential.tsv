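name	ri	p_anova	q_value	content_a	content_b	content_c
2-Methyldecane	1053	0.012	0.363	1.13 ± 0.18	2.92 ± 1.26	1.23 ± 0.44
Dodecane, 2,6,10-trimethyl-	1140	0.035	0.623	0.78 ± 0.68	3.68 ± 1.73	1.82 ± 1.05
P-menthan-1-ol	1413	0.018	0.498	2.25 ± 0.75	0.80 ± 0.59	1.77 ± 1.85
(E)-2-Octenal	1418	0.001	0.333	0.56 ± 0.07	0.40 ± 0.09	ND
1-Octen-3-one	1433	0.044	0.623	2.73 ± 0.45	3.88 ± 1.04	1.51 ± 1.48
6-Undecanone	1521	0.022	0.498	0.51 ± 0.10	0.09 ± 0.18	0.29 ± 0.37
Heptacosane	1622	0.025	0.517	ND	ND	0.22 ± 0.39
2-Acetyl-1h-pyrrole	1956	0.007	0.498	0.06 ± 0.06	ND	0.02 ± 0.00
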