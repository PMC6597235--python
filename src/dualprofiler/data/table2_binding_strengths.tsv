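target_id	compound_id	rank	n_hbonds	n_nonbonded	n_residues	dock_score	binding_energy	pkd
PI3Kgamma	XL765		0	28	10	-35.16	-7.89	5.79
PI3Kgamma	28	1	2	37	13	-48.59	-9.14	6.70
PI3Kgamma	18	5	1	45	13	-45.12	-8.49	6.23
PI3Kgamma	38	6	4	37	13	-42.95	-9.98	7.32
PI3Kgamma	9	14	0	38	10	-39.45	-7.82	5.73
PI3Kgamma	10	20	2	52	11	-34.44	-8.49	6.23
PI3Kgamma	19	16	2	24	8	-38.32	-7.45	5.46
PI3Kgamma	Native		3	51	13		-10.28	7.54
mTOR	XL765		1	37	11	-41.17	-8.56	6.28
mTOR	28	5	0	31	11	-48.32	-9.16	6.71
mTOR	18	7	2	39	15	-46.96	-8.80	6.45
mTOR	38	12	0	31	10	-44.91	-8.82	6.47
mTOR	9	9	0	30	10	-46.26	-8.23	6.03
mTOR	10	11	2	26	11	-45.91	-8.71	6.39
mTOR	19	16	1	42	13	-43.70	-9.46	6.94
mTOR	Native		3	46	11		-8.88	6.51
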