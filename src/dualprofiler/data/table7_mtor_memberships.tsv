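compound	residue
XL765	Ile-2163
XL765	Leu-2185
XL765	Trp-2239
XL765	Val-2240
XL765	Asp-2244
XL765	Thr-2245
XL765	Ala-2248
XL765	Arg-2251
XL765	Asp-2252
XL765	Met-2345
XL765	Ile-2356
28	Ser-2165
28	Gln-2167
28	Leu-2185
28	Glu-2190
28	Ile-2237
28	Gly-2238
28	Trp-2239
28	Val-2240
28	Met-2345
28	Ile-2356
28	Asp-2357
18	Ile-2163
18	Leu-2185
18	Tyr-2225
18	Ile-2237
18	Gly-2238
18	Trp-2239
18	Val-2240
18	Cys-2243
18	Asp-2244
18	Thr-2245
18	His-2247
18	Ala-2248
18	Arg-2251
18	Ser-2342
18	Ile-2356
38	Ser-2165
38	Lys-2166
38	Gln-2167
38	Pro-2169
38	Leu-2185
38	Lys-2187
38	Trp-2239
38	Thr-2245
38	Met-2345
38	Ile-2356
9	Thr-2164
9	Gln-2167
9	Leu-2185
9	Lys-2187
9	Glu-2190
9	Gly-2238
9	Val-2240
9	Met-2345
9	Ile-2356
9	Asp-2357
10	Ile-2163
10	Pro-2169
10	Leu-2185
10	Tyr-2225
10	Ile-2237
10	Gly-2238
10	Trp-2239
10	His-2247
10	Ser-2342
10	Met-2345
10	Ile-2356
19	Ile-2163
19	Pro-2169
19	Leu-2185
19	Lys-2187
19	Glu-2190
19	Leu-2192
19	Asp-2195
19	Tyr-2225
19	Ile-2237
19	Trp-2239
19	Met-2345
19	Ile-2356
19	Asp-2357
Native	Ile-2163
Native	Leu-2185
Native	Glu-2190
Native	Asp-2195
Native	Tyr-2225
Native	Ile-2237
Native	Gly-2238
Native	Trp-2239
Native	Val-2240
Native	Ile-2356
Native	Asp-2357
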