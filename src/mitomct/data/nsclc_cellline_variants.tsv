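# ND-gene variants detected in NSCLC cell lines (human mtDNA coordinates)
sample	position	ref	alt	kind	heteroplasmy
H358	13708	G	A	substitution	1.0
H358	4216	T	C	substitution	1.0
RERF-Lc-Ad2	11453	G	A	substitution	1.0
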