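# mitomct

Tools for linking pathogenic mitochondrial NADH dehydrogenase (*ND*) gene
mutations to MCT4 (SLC16A3) expression in cancer: mtDNA variant annotation
under the vertebrate mitochondrial genetic code, rule-based pathogenicity
classification from six published criteria, a two-condition RNA-seq
contrast with KEGG-style pathway summarisation, and the cohort association
statistics that connect mutation status to MCT4 immunohistochemistry.
A synthetic-data generator emulates every input, so the whole pipeline runs
and is testable without downloads.

Intended users: cancer-genomics and mitochondrial-biology analysts who need
a small, fully tested re-implementation of this analysis chain rather than
a general-purpose variant or expression toolkit.

## What it computes

**Variant annotation.** A variant such as m.11453G>A is resolved against a
circular mitochondrial reference with 1-based coordinates. For a protein
gene on the heavy strand the affected codon is `offset // 3 + 1` with
`offset = pos - start`; for light-strand genes (e.g. *ND6*) the allele is
complemented and the offset measured from the gene end. Translation uses
the vertebrate mitochondrial code (AGA/AGG stop, TGA Trp, ATA Met). Indels
with length not divisible by 3 are frameshifts.

**Pathogenicity.** Each missense change is scored against: Grantham
distance > 50 (computed from the 1974 physicochemical formula
D = ρ·[α·Δc² + β·Δp² + γ·Δv²]^½ with ρ normalising the mean pair distance
to 100), MutPred score > 0.7, conservation of the original residue,
predicted conformational change, reported mitochondrial-disease
association, and mtROS overproduction — the last three consumed as
external evidence flags. The default aggregation rule is

    protein_truncating OR mutpred OR (grantham AND conformational_change)

evaluated with three-valued logic so missing evidence propagates; rules are
user-configurable expressions and every call records which rule fired.

**Expression contrast.** Counts → CPM (per-sample, columns sum to 10⁶),
logFC = log₂(CPM_test + c) − log₂(CPM_ref + c) with pseudocount c = 0.5,
RSD = |logFC|; pathway over-representation by one-sided Fisher exact
(hypergeometric) tests at the predefined level p < 0.01, and per-pathway
arithmetic mean logFC.

**Association statistics.** Five-bin IHC grades (−, +, ++, +++, ++++ for
0, 1–10, 11–50, 51–90, > 90 % positive cells), "strongly positive" = ≥ +++,
the Yates-continuity-corrected χ² on the mutation × strong-MCT4 2×2 table,
and a tie-aware exact Mann–Whitney U (full enumeration for n₁+n₂ ≤ 16) for
per-mouse metastasis counts.

## Worked example

```python
from mitomct import (VERTEBRATE_MITO, Variant, annotate_variant,
                     builtin_reference, builtin_cohort,
                     build_mutation_mct4_table, chi2_yates)

genome, genes = builtin_reference("human")
eff = annotate_variant(genome, genes, VERTEBRATE_MITO,
                       Variant(11453, "G", "A", "substitution"))
print(eff)
# CodingEffect(gene='ND4', codon_index=232, ref_aa='A', alt_aa='T',
#              effect_class='missense')

table = build_mutation_mct4_table(builtin_cohort())
print(table.tolist())          # [[8, 1], [1, 7]]
res = chi2_yates(table.tolist())
print(round(res.chi2, 3), round(res.p, 5))
# 7.091 0.00775
```

The annotation reads: the G→A change at position 11453 falls in *ND4* at
residue 232 and substitutes threonine for alanine (A232T). The packaged
17-tissue NSCLC cohort yields 8 of 9 mutation-bearing tissues strongly
MCT4-positive versus 1 of 8 without mutations, significant at p < 0.05
under the Yates-corrected χ² test.

The built-in references use the real rCRS (human) and NC_005089 (mouse)
gene coordinates with a synthetic background sequence carrying the true
reference codons at the variant sites of interest; any real genome FASTA
and gene-coordinate TSV can be supplied instead.

## Command line

```
mitomct simulate   --seed 7 --out-dir sim/          # synthetic inputs + truth
mitomct annotate   --genome sim/genome.fasta --gene-table sim/genes.tsv \
                   --variants sim/variants.tsv --out-dir out/
mitomct expression --counts sim/counts.tsv --conditions ref_1=ref,test_1=test \
                   --gmt sim/pathways.gmt --out-dir out/
mitomct association --cohort sim/cohort.tsv --out-dir out/
mitomct all        --config config.yaml --out-dir out/
```

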