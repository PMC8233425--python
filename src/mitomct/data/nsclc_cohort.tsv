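# Published 17-tissue NSCLC cohort: MCT4 immunohistochemistry versus predicted
# pathogenic ND-gene mutation status (P = primary tumour, M = metastasis).
# mutation_status is input truth for the association stage; empty cells = not reported.
id	histology	site	gene	mutation	aa_change	conserved	mutpred	disease_association	mutation_status	ihc_score
LuAdBrM5	Adenocarcinoma	M	ND1	T3394C	Y30H	yes	0.783	LHON/Diabetes/CPT deficiency/High altitude adaptation	homoplasmy	++++
LuAdBrM8	Adenocarcinoma	M	ND1	T3394C	Y30H	yes	0.783	LHON/Diabetes/CPT deficiency/High altitude adaptation	homoplasmy	+++
LuAdBrM13	Adenocarcinoma	M	ND1	T3394C	Y30H	yes	0.783	LHON/Diabetes/CPT deficiency/High altitude adaptation	homoplasmy	+++
LgCa196	Adenocarcinoma	P	ND1	C3497T	A64V		0.413	LHON	homoplasmy	+++
LuAdBrM2	Adenocarcinoma	M	ND1	C3497T	A64V		0.413	LHON	homoplasmy	++++
LuPoBrM1	Adenocarcinoma	M	ND1	C3497T	A64V		0.413	LHON	homoplasmy	+++
LgCa169	Squamous cell carcinoma	P	ND1	G3709A	A135T	yes	0.774		heteroplasmy_or_heterogeneous	- and ++++
LuAdBrM1	Adenocarcinoma	M	ND5	C12813A	Y159stop				heteroplasmy_or_heterogeneous	++++
LgCa173	Squamous cell carcinoma	P	ND5	G13103A	G256E	yes	0.834		heteroplasmy_or_heterogeneous	++
LgCa157	Squamous cell carcinoma	P							none	+++
LgCa179	Adenocarcinoma	P							none	++ (local)
LgCa183	Squamous cell carcinoma	P							none	+
LgCa188	Squamous cell carcinoma	P							none	+
LgCa193	Squamous cell carcinoma	P							none	+
LgCa202	Adenocarcinoma	P							none	+
LgCa175	Adenocarcinoma	P							none	+
LgCa195	Bronchioalveolar carcinoma	P							none	+
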