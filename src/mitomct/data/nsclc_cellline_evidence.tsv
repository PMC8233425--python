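# External evidence for the NSCLC cell-line variants, encoding the qualitative
# adjudication statements: numeric MutPred scores were not printed, so the
# qualitative mutpred_high column stands in when the score column is empty.
sample	position	alt	mutpred	mutpred_high	conserved	conformational_change	disease_associated	mtros_overproduction
H358	13708	A			yes	yes	yes	yes
H358	4216	C		no		no	yes
RERF-Lc-Ad2	11453	A		yes	yes		yes	yes
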