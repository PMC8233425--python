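"""Synthetic inputs with the statistical structure the pipeline assumes.

Each generator emulates one of the study's data shapes: a circular
mitochondrial genome with H- and L-strand protein genes carrying
planted substitutions and insertions; a two-condition RNA-seq count
matrix (negative-binomial counts around log-normal gene baselines,
single library per condition as in the cybrid contrast) with planted
up/down-regulated genes and an optional pathway-level shift; a
17-tissue-style cohort in which mutation-bearing tissues draw their
MCT4-positive percentage from a higher scaled-Beta distribution; and
per-mouse pulmonary metastasis counts for two groups of 6 and 7 animals
with negative-binomial means matching the published medians (0.5 vs 38).

Every dataset ships a :class:`PlantedTruth` sidecar sufficient to score
recovery without re-reading the config, and a fixed seed yields
byte-identical outputs.  One global seed spawns independent per-stage
substreams, so stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .association import TissueRecord, ihc_score_from_percent
from .expression import CountMatrix, PathwayCatalog
from .reference import GeneFeature, MitoGenome, reverse_complement
from .variants import Variant

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "synth_genome",
    "synth_counts",
    "synth_catalog",
    "synth_cohort",
    "synth_metastasis",
]

_STAGES = ("genome", "counts", "cohort", "metastasis", "catalog")


@dataclass
class GeneratorConfig:
    """Defaults encode the study conditions each stage emulates."""

    seed: int = 0
    # genome stage
    genome_length: int = 16299
    gene_layout: tuple = (
        # (name, start, end, strand) protein genes; mouse-style layout
        ("ND1", 2751, 3707, "H"),
        ("ND2", 3914, 4951, "H"),
        ("COI", 5328, 6872, "H"),
        ("ND3", 9459, 9806, "H"),
        ("ND4", 10167, 11544, "H"),
        ("ND5", 11742, 13565, "H"),
        ("ND6", 13570, 14070, "L"),
    )
    n_substitutions: int = 3
    n_insertions: int = 1
    # counts stage
    n_genes: int = 2000
    n_samples_per_condition: int = 1
    baseline_log_mean: float = 6.0   # natural-log scale of expected counts
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.1       # var = mu + dispersion * mu^2
    planted_min_baseline: float = 50.0  # planted genes are detectably expressed
    planted_de: tuple = (
        # the five most upregulated genes of the cybrid contrast, led by Slc16a3
        ("Slc16a3", 6.0),
        ("Col6a3", 5.0),
        ("Col5a3", 4.5),
        ("Krt8", 4.0),
        ("Gatm", 3.5),
    )
    planted_pathway_shift: tuple | None = None  # (pathway_id, mean logFC)
    # pathway catalogue stage
    n_pathways: int = 50
    pathway_size: int = 40
    # cohort stage
    n_tissues: int = 17
    mutation_prevalence: float = 9 / 17
    ihc_beta_mutation: tuple = (6.0, 1.5)   # scaled to [0, 100]; mostly strong
    ihc_beta_none: tuple = (1.2, 6.0)       # mostly weak
    # metastasis stage
    group_sizes: tuple = (6, 7)
    metastasis_means: tuple = (0.5, 38.0)
    metastasis_dispersion: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.mutation_prevalence < 1:
            raise ValueError("mutation prevalence must lie in (0, 1)")
        for name in ("n_genes", "n_samples_per_condition", "n_tissues", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        last_end = 0
        for name, start, end, strand in self.gene_layout:
            if start <= last_end:
                raise ValueError(f"gene layout overlaps or is unsorted at {name}")
            if end > self.genome_length:
                raise ValueError(f"gene layout overflows the genome at {name}")
            last_end = end

    def rng(self, stage: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[_STAGES.index(stage)])


@dataclass
class PlantedTruth:
    """Realised planted parameters, serialisable alongside the data."""

    stage: str
    entries: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        raw = json.loads(text)
        return cls(stage=raw["stage"], entries=raw["entries"])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def synth_genome(
    config: GeneratorConfig,
) -> tuple[MitoGenome, list[GeneFeature], list[Variant], PlantedTruth]:
    """Random circular genome with planted coding variants.

    Substitutions are drawn inside protein genes away from incomplete
    terminal codons; the true coding effect of each planted variant is
    recorded in the truth sidecar via direct codon bookkeeping
    (Biopython translation table 2), independent of the annotation
    code path.
    """
    rng = config.rng("genome")
    seq = list(rng.choice(list("ACGT"), size=config.genome_length))
    features = [
        GeneFeature(name, start, end, strand, "protein")
        for name, start, end, strand in config.gene_layout
    ]
    variants: list[Variant] = []
    truth = PlantedTruth(stage="genome")

    genes = list(features)
    for i in range(config.n_substitutions):
        feat = genes[rng.integers(len(genes))]
        n_codons = feat.length // 3
        codon_index = int(rng.integers(1, n_codons + 1))
        pos_in_codon = int(rng.integers(3))
        offset = 3 * (codon_index - 1) + pos_in_codon
        position = feat.start + offset if feat.strand == "H" else feat.end - offset
        ref = seq[position - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        # coding-strand codon before/after, independent of the annotator
        if feat.strand == "H":
            cstart = feat.start + 3 * (codon_index - 1)
            codon = "".join(seq[cstart - 1 : cstart + 2])
            mutated = list(codon)
            mutated[pos_in_codon] = alt
        else:
            cend = feat.end - 3 * (codon_index - 1)
            codon = reverse_complement("".join(seq[cend - 3 : cend]))
            mutated = list(codon)
            mutated[pos_in_codon] = reverse_complement(alt)
        ref_aa = str(Seq(codon).translate(table=2))
        alt_aa = str(Seq("".join(mutated)).translate(table=2))
        if ref_aa == alt_aa:
            klass = "synonymous"
        elif alt_aa == "*":
            klass = "nonsense"
        elif ref_aa == "*":
            klass = "missense"
        else:
            klass = "missense"
        v = Variant(position, ref, alt, "substitution", heteroplasmy=1.0, sample="synthetic")
        variants.append(v)
        truth.entries.append(
            {
                "label": v.label,
                "gene": feat.name,
                "codon_index": codon_index,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "effect_class": klass,
            }
        )

    for i in range(config.n_insertions):
        feat = genes[rng.integers(len(genes))]
        position = int(rng.integers(feat.start, feat.end))
        base = str(rng.choice(list("ACGT")))
        v = Variant(position, "", base, "insertion", heteroplasmy=1.0, sample="synthetic")
        variants.append(v)
        truth.entries.append(
            {
                "label": v.label,
                "gene": feat.name,
                "codon_index": None,
                "ref_aa": None,
                "alt_aa": None,
                "effect_class": "frameshift",
            }
        )

    genome = MitoGenome(accession="synthetic-mt", species="synthetic", sequence="".join(seq))
    return genome, features, variants, truth


def synth_catalog(config: GeneratorConfig, genes: Sequence[str]) -> PathwayCatalog:
    """Random pathway catalogue over the given gene universe."""
    rng = config.rng("catalog")
    pathways = {}
    genes = list(genes)
    size = min(config.pathway_size, len(genes))
    for i in range(config.n_pathways):
        members = rng.choice(genes, size=size, replace=False)
        pid = f"path{i:04d}"
        pathways[pid] = (pid, frozenset(members.tolist()))
    return PathwayCatalog(pathways, universe=frozenset(genes))


def synth_counts(
    config: GeneratorConfig, catalog: PathwayCatalog | None = None
) -> tuple[CountMatrix, PlantedTruth]:
    """Two-condition count matrix with planted differential expression.

    Gene baselines are log-normal; counts are negative binomial around
    the baseline, with planted genes shifted by 2**log2fc in the test
    condition.  If a pathway shift is configured its members are shifted
    by the pathway mean logFC.
    """
    rng = config.rng("counts")
    planted = dict(config.planted_de)
    n_background = config.n_genes - len(planted)
    genes = list(planted) + [f"gene{i:05d}" for i in range(n_background)]
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    )
    log2fc = np.zeros(config.n_genes)
    for i, g in enumerate(genes):
        if g in planted:
            log2fc[i] = planted[g]
            baseline[i] = max(baseline[i], config.planted_min_baseline)
    truth = PlantedTruth(stage="counts")
    if config.planted_pathway_shift is not None:
        if catalog is None:
            raise ValueError("a pathway shift needs a catalogue")
        pid, shift = config.planted_pathway_shift
        members = catalog.pathways[pid][1]
        for i, g in enumerate(genes):
            if g in members and g not in planted:
                log2fc[i] += shift
        truth.entries.append({"kind": "pathway_shift", "pathway": pid, "mean_log2fc": shift})

    k = config.n_samples_per_condition
    cols = {}
    conditions = {}
    for j in range(k):
        name = f"ref_{j + 1}"
        cols[name] = _nb_draw(rng, baseline, config.nb_dispersion)
        conditions[name] = "ref"
    test_mu = baseline * np.power(2.0, log2fc)
    for j in range(k):
        name = f"test_{j + 1}"
        cols[name] = _nb_draw(rng, test_mu, config.nb_dispersion)
        conditions[name] = "test"

    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    for g, fc in planted.items():
        truth.entries.append({"kind": "de_gene", "gene": g, "log2fc": fc})
    return CountMatrix(counts, conditions), truth


def synth_cohort(config: GeneratorConfig) -> tuple[list[TissueRecord], PlantedTruth]:
    """Cohort tissues with a mutation -> MCT4-positivity effect.

    Mutation status is Bernoulli at the configured prevalence; the
    percentage of MCT4-positive cells is drawn from a status-specific
    Beta scaled to [0, 100] and binned into the five-grade score.
    """
    rng = config.rng("cohort")
    records = []
    truth = PlantedTruth(stage="cohort")
    for i in range(config.n_tissues):
        bearing = bool(rng.random() < config.mutation_prevalence)
        a, b = config.ihc_beta_mutation if bearing else config.ihc_beta_none
        percent = float(rng.beta(a, b) * 100)
        status = "homoplasmy" if bearing else "none"
        rec = TissueRecord(
            id=f"T{i:03d}",
            histology="synthetic",
            site="P",
            mutation_status=status,
            ihc_percent=percent,
            ihc_score=ihc_score_from_percent(percent),
        )
        records.append(rec)
        truth.entries.append(
            {"id": rec.id, "mutation_bearing": bearing, "ihc_percent": percent}
        )
    return records, truth


def synth_metastasis(config: GeneratorConfig) -> tuple[list[int], list[int], PlantedTruth]:
    """Per-animal pulmonary metastasis counts for two groups."""
    rng = config.rng("metastasis")
    n1, n2 = config.group_sizes
    mu1, mu2 = config.metastasis_means
    g1 = _nb_draw(rng, np.full(n1, mu1), config.metastasis_dispersion).astype(int).tolist()
    g2 = _nb_draw(rng, np.full(n2, mu2), config.metastasis_dispersion).astype(int).tolist()
    truth = PlantedTruth(
        stage="metastasis",
        entries=[
            {"group": 1, "mean": mu1, "n": n1, "counts": g1},
            {"group": 2, "mean": mu2, "n": n2, "counts": g2},
        ],
    )
    return g1, g2, truth
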