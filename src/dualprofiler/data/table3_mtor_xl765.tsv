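residue	n_nonbonded	delta_asa	n_hbonds
Ile-2163	2	27.24	0
Leu-2185	1	25.32	0
Trp-2239	10	56.39	0
Val-2240	1	8.9	0
Asp-2244	3	28.52	0
Thr-2245	1	27.82	0
Ala-2248	1	16.09	0
Arg-2251	6	55.76	1
Asp-2252	3	24.43	0
Met-2345	6	30.62	0
Ile-2356	3	31.64	0
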