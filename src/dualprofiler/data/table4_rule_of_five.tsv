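property	desired_below	XL765	28	18	38	9	10	19
mol_weight	500	599.67	497.53	473.49	690.42	501.55	493.55	491.58
hbd	5	3	2	4	3	2	4	4
hba	10	9	7	8	8	8	9	9
rotatable_bonds	10	10	6	6	7	8	6	6
logp	5	5.76	4.29	3.53	4.73	4.14	3.42	3.18
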