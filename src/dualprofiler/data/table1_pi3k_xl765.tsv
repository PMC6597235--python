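residue	n_nonbonded	delta_asa
Lys-802	3	48.45
Met-804	1	25.32
Trp-812	5	49.81
Ile-831	1	22.3
Val-882	2	14.1
Ala-885	2	26.79
Thr-886	1	22.98
Lys-890	4	59.19
Met-953	8	35.83
Ile-963	1	20.35
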