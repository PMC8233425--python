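# Methods

## Reference model and coordinates

Mitochondrial genomes are modelled as circular sequences with 1-based
inclusive coordinates, matching mtDNA nomenclature in which `G13997A`
names the reference G at position 13997. Heavy (H) strand is the
reference orientation; light-strand (L) genes are read as the reverse
complement, so an L-strand coding offset is measured from the gene end
and alleles are complemented. Origin-spanning features are rejected —
no gene used anywhere in this package spans the origin — and the
incomplete terminal codons common in mtDNA (completed in vivo by
polyadenylation) are flagged as untranslated tails rather than errors;
a substitution landing in such a tail is reported non-coding with a
warning.

Two gene tables ship with the package: the human rCRS (NC_012920) and
mouse (NC_005089) protein-gene annotations plus the two rRNAs. The
built-in *reference genomes* are deterministic synthetic stand-ins:
real coordinates, pseudo-random background sequence, and the true
reference codons planted at every variant position the package's
examples and fixtures exercise (human 3394, 3497, 3709, 4216, 11453,
12813, 13103, 13708; mouse 6589, 13891, 13997). Coordinate arithmetic
and the documented amino-acid changes are therefore exact, while
translation of whole genes outside those sites is not biologically
meaningful. Users with the real FASTA files can pass them to
`load_genome` unchanged.

Protein genes may overlap (ATP8/ATP6, ND4L/ND4); annotation takes the
first matching feature in table order and warns, which reproduces the
convention that positions in the ND4L/ND4 overlap are reported against
the first-listed gene.

## Pathogenicity criteria and rule

The Grantham table is computed, not stored: distances follow
D = ρ·[α(c₁−c₂)² + β(p₁−p₂)² + γ(v₁−v₂)²]^½ with α = 1.833,
β = 0.1018, γ = 0.000399 over the published composition/polarity/volume
properties, with ρ = 100 / (mean raw pair distance) = 50.78988 and
rounding to integers. This reproduces the canonical values (A–T 58,
Y–H 83, W–C 215, L–I 5); the historically printed matrix is known to
disagree with its own formula by ±1 on a few pairs (e.g. S–R, M–L), and
this package follows the formula.

Criterion comparisons are strict: Grantham > 50 and MutPred > 0.7, so a
score of exactly 0.7 does not qualify. When a numeric MutPred score is
unavailable but a qualitative above-threshold judgement was reported,
the evidence record carries it as a boolean (`mutpred_high`).
Conservation is the fraction of species sharing the reference residue
(default threshold 1.0, i.e. strict unanimity; gap-only columns are
indeterminate).

No published combination rule exists for the six criteria, so the
default rule is the minimal one consistent with the three adjudicated
cell-line variants: `protein_truncating or mutpred or (grantham and
conformational_change)`. Nonsense and frameshift effects bypass the
missense criteria through the protein-truncating flag. mtROS
overproduction is a cell-level, not per-variant, measurement: it is
carried and reported but not referenced by the default rule, since it
cannot discriminate two variants within one cell line. Rules are
arbitrary boolean expressions over the criterion names, evaluated in
Kleene three-valued logic; a verdict is `indeterminate` only when every
evidence flag the rule references is missing, otherwise an unsatisfied
rule yields `not_predicted`. Homoplasmy is declared at heteroplasmy
fraction ≥ 0.95 (configurable) or when the fraction is unrecorded.

In the cohort association stage the tissue-level mutation status is
taken from the input table rather than recomputed: the published cohort
contains a mutation-bearing tissue (MutPred 0.413, disease-associated
only) that no deterministic function of the listed criteria admits
while also excluding the adjudicated non-pathogenic cell-line variant.

## Expression contrast

CPM is a within-sample normalisation (counts / library size × 10⁶).
The contrast is defined on per-condition mean CPM, so one or more
libraries per condition are accepted; logFC = log₂(mean CPM_test + c) −
log₂(mean CPM_ref + c). The pseudocount c defaults to 0.5 CPM — the
source analysis does not state one, and 0.5 bounds the logFC of genes
with zero counts while shifting well-expressed genes negligibly. RSD,
the square root of the squared difference, reduces to |logFC| and is
asserted as an identity in the tests. Ranking is a stable sort with
lexicographic tie-breaks.

Enrichment is a one-sided over-representation (hypergeometric upper
tail) per pathway with the catalogue universe — all genes appearing in
any pathway of the collection — as the background, at a predefined
significance level p < 0.01 with no multiple-testing correction (a
fixed level, not an FDR, is the stated convention). Symbol matching is
case-sensitive exact match after whitespace stripping; dropped symbols
are logged, never silently discarded.

## Association statistics

IHC grades bin the percentage of MCT4-positive cancer cells with upper
boundaries inclusive in the lower bin (10 → +, 50 → ++, 90 → +++).
"Strongly positive" is interpreted as grade ≥ +++, which is the reading
under which the published count of 8 strong positives (several scored
exactly +++) is self-consistent. Mixed printed entries such as
"− and ++++" resolve to their maximum component, and qualifiers such as
"++ (local)" to the graded component.

The 2×2 test is the Yates-corrected χ²,
N·(max(0, |ad−bc| − N/2))² / ((a+b)(c+d)(a+c)(b+d)) on 1 df, with the
continuity correction clamped at zero and zero margins rejected as
undefined. The Mann–Whitney U uses midranks; for n₁+n₂ ≤ 16 the
two-sided p is the exact share of all C(n₁+n₂, n₁) group labelings
whose U deviates from the null mean n₁n₂/2 at least as far as observed
(tie-aware, so identical groups give p = 1); larger samples use the
normal approximation with tie correction, and the method used is
recorded in the result.

## Synthetic data

The generators emulate the study's data shapes; a fixed seed yields
byte-identical output, and one global seed spawns independent substreams
per stage (numpy `SeedSequence.spawn`), so stages regenerate
independently. Every dataset is accompanied by a planted-truth sidecar
sufficient to score recovery without re-reading the config.

* **Genome stage** — a random circular genome over a mouse-style,
  non-overlapping H/L protein-gene layout, with planted substitutions
  (effects recorded by direct codon bookkeeping through Biopython's
  translation table 2 — a code path independent of the annotator) and
  single-base insertions (frameshifts by construction).
* **Counts stage** — negative-binomial counts (var = μ + φμ², φ = 0.1)
  around log-normal gene baselines (ln-mean 6, ln-sd 1.5 over 2 000
  genes, ≈ 2.5 M reads per library), one library per condition as in
  the cybrid contrast. Planted genes default to the five top
  upregulated symbols of that contrast, led by Slc16a3 at +6 log₂
  units, and are floored at a baseline of 50 expected counts because
  they emulate genes expressed at clearly detectable levels; an
  optional pathway-level mean shift can be planted against a generated
  catalogue.
* **Cohort stage** — 17 tissues at mutation prevalence 9/17; the
  MCT4-positive percentage is Beta-distributed scaled to [0, 100]
  (Beta(6, 1.5) for mutation-bearing, Beta(1.2, 6) for mutation-free),
  giving strong-positive rates comparable to the published 8/9 vs 1/8.
* **Metastasis stage** — negative-binomial counts for groups of 6 and
  7 animals with means 0.5 and 38, the published medians of the
  wild-type and frameshift-mutant cybrids.

What the generators do *not* emulate: gene–gene correlation, library
composition effects, GC/length biases, batch structure, or spatial IHC
heterogeneity. Passing recovery and calibration tests therefore shows
the pipeline's statistics behave correctly under their own model
assumptions, not that the biological conclusions would replicate on
raw data.

## Problem sizes and numerical choices

The test suite and acceptance script run at reduced, seeded problem
sizes chosen as the package's own defaults: 1 000 random variants for
the annotation oracle, universes ≤ 30 with all achievable overlaps for
the exhaustive Fisher check, 15 random small samples for the exact
Mann–Whitney enumeration, 3 000 random pathways for the null-enrichment
calibration (whose rejection rate is compared against the exact
discrete hypergeometric level rather than α itself, since achievable
p-values are discrete), and 60 replicates for the metastasis power and
type-I checks. Floating-point comparisons in the exact enumerations use
a 10⁻⁹ slack when comparing tie-affected U deviations.

## Known limitations

* Multi-nucleotide substitutions and compound haplotypes are out of
  scope; in-frame indels are classified (`inframe_indel`) but not
  residue-resolved.
* The evidence criteria that come from external predictors
  (MutPred, SWISS-MODEL conformational calls, MITOMAP disease
  associations) are consumed as inputs; this package does not run
  those tools.
* The expression stage implements the stated log₂-CPM-difference
  definition directly; it does not reproduce moderated-statistics
  normalisations from differential-expression toolkits.
* The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and is capped
  at n₁+n₂ = 16 before switching to the normal approximation.
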