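compound	residue
XL765	Lys-802
XL765	Met-804
XL765	Trp-812
XL765	Ile-831
XL765	Val-882
XL765	Ala-885
XL765	Thr-886
XL765	Lys-890
XL765	Met-953
XL765	Ile-963
28	Met-804
28	Ser-806
28	Trp-812
28	Ile-831
28	Ile-879
28	Ala-885
28	Thr-887
28	Lys-890
28	Asp-950
28	Asn-951
28	Met-953
28	Ile-963
28	Asp-964
18	Met-804
18	Ala-805
18	Ser-806
18	Ile-831
18	Lys-833
18	Tyr-867
18	Ile-879
18	Thr-887
18	Lys-890
18	Asp-950
18	Met-953
18	Ile-963
18	Asp-964
38	Met-804
38	Ser-806
38	Lys-807
38	Trp-812
38	Ile-879
38	Ala-885
38	Lys-890
38	Asp-950
38	Met-953
38	Ile-963
38	Asp-964
38	His-967
38	Leu-1090
9	Ser-806
9	Lys-807
9	Ile-831
9	Lys-833
9	Asp-964
9	His-967
9	His-1089
9	Leu-1090
9	Val-1091
9	Leu-1092
10	Met-804
10	Ala-805
10	Ser-806
10	Lys-833
10	Tyr-867
10	Ile-879
10	Thr-887
10	Lys-890
10	Asp-950
10	Met-953
10	Ile-963
10	Asp-964
19	Ala-805
19	Ser-806
19	Lys-890
19	Asp-950
19	Asn-951
19	Asp-964
19	His-967
19	Leu-1090
19	Val-1091
Native	Met-804
Native	Trp-812
Native	Ile-831
Native	Lys-833
Native	Tyr-867
Native	Ile-879
Native	Glu-880
Native	Ile-881
Native	Val-882
Native	Thr-887
Native	Met-953
Native	Ile-963
Native	Asp-964
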