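"""Circular mitochondrial reference genomes, gene coordinates and the
vertebrate mitochondrial genetic code.

Coordinates are 1-based and inclusive throughout, matching the mtDNA
community convention in which ``G13997A`` names the substitution of the
reference G at position 13997.  Heavy (H) strand is the reference
orientation; light (L) strand genes are read as the reverse complement.

Vertebrate mitochondrial translation differs from the standard code at
four codons (AGA/AGG are stops, ATA is Met, TGA is Trp); the table is
built from Biopython's published translation table 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Union

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "MitoGenome",
    "GeneFeature",
    "GeneticCode",
    "VERTEBRATE_MITO",
    "FormatError",
    "reverse_complement",
    "load_genome",
    "load_gene_table",
    "builtin_gene_table",
    "builtin_reference",
    "extract_cds",
    "translate",
]

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (FASTA, TSV, VCF)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MitoGenome:
    """A circular mitochondrial genome sequence with an identifier."""

    accession: str
    species: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty genome sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise FormatError(f"illegal symbols in genome sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside genome [1, {self.length}]")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene on the mitochondrial genome, 1-based inclusive coordinates.

    ``strand`` is ``H`` (heavy, reference orientation) or ``L`` (light,
    reverse complement).  ``kind`` is one of protein/tRNA/rRNA/control.
    """

    name: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if self.kind not in ("protein", "tRNA", "rRNA", "control"):
            raise ValueError(f"{self.name}: unknown feature kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.name}: invalid coordinates [{self.start}, {self.end}] "
                "(origin-spanning features are not supported)"
            )
        if self.kind == "protein" and self.length < 3:
            raise ValueError(f"{self.name}: protein feature shorter than one codon")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> one-letter amino acid map; stop codons map to '*'."""

    table: dict = field(repr=False)
    id: str = "vertebrate mitochondrial"

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.table)}")

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]


def _vertebrate_mito_code() -> GeneticCode:
    bio = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
    table = dict(bio.forward_table)
    for codon in bio.stop_codons:
        table[codon] = "*"
    return GeneticCode(table=table)


VERTEBRATE_MITO = _vertebrate_mito_code()


def load_genome(fasta_source: Union[str, IO[str]], species: str = "") -> MitoGenome:
    """Read a single-record FASTA into a :class:`MitoGenome`.

    The first whitespace-delimited header token becomes the accession.
    Multi-record files are rejected.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return MitoGenome(accession=rec.id, species=species, sequence=str(rec.seq).upper())


def load_gene_table(source: Union[str, IO[str]], genome_length: int | None = None) -> list[GeneFeature]:
    """Read gene features from a TSV with columns name/start/end/strand/kind.

    Lines starting with ``#`` are comments.  If ``genome_length`` is given,
    features extending past it are rejected.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    features: list[GeneFeature] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["name", "start", "end", "strand", "kind"]
            if header != expected:
                raise FormatError(f"gene table header must be {expected}, got {header}")
            continue
        if len(fields) != 5:
            raise FormatError(f"line {lineno}: expected 5 tab-separated fields")
        name, start, end, strand, kind = fields
        try:
            feat = GeneFeature(name, int(start), int(end), strand, kind)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        if genome_length is not None and feat.end > genome_length:
            raise FormatError(f"line {lineno}: {name} extends past genome length {genome_length}")
        features.append(feat)
    return features


def builtin_gene_table(species: str) -> list[GeneFeature]:
    """Packaged gene coordinate tables: ``human`` (rCRS, NC_012920
    annotation) or ``mouse`` (NC_005089 annotation)."""
    fname = {"human": "human_mt_genes.tsv", "mouse": "mouse_mt_genes.tsv"}.get(species)
    if fname is None:
        raise ValueError(f"no builtin gene table for {species!r} (use 'human' or 'mouse')")
    text = resources.files("mitomct.data").joinpath(fname).read_text()
    import io

    return load_gene_table(io.StringIO(text))


# Genome lengths of the real references whose coordinate systems the
# builtin tables use.
_GENOME_LENGTH = {"human": 16569, "mouse": 16299}

# Reference codons at the variant sites adjudicated in the study, as
# (codon start position on the H strand, H-strand codon bases).  For
# L-strand genes the coding codon is the reverse complement.
_PLANTED_CODONS = {
    "human": [
        (3394, "TAC"),   # ND1 Y30   (T3394C -> Y30H)
        (3496, "GCC"),   # ND1 A64   (C3497T -> A64V)
        (3709, "GCC"),   # ND1 A135  (G3709A -> A135T)
        (4216, "TAC"),   # ND1 Y304  (T4216C -> Y304H)
        (11453, "GCC"),  # ND4 A232  (G11453A -> A232T)
        (12811, "TAC"),  # ND5 Y159  (C12813A -> Y159*)
        (13102, "GGA"),  # ND5 G256  (G13103A -> G256E)
        (13708, "GCC"),  # ND5 A458  (G13708A -> A458T)
    ],
    "mouse": [
        (6588, "GTA"),   # COI V421  (T6589C -> V421A)
        (13996, "TGG"),  # ND6 P25 on the L strand (G13997A -> P25L)
    ],
}


def builtin_reference(species: str, seed: int = 2021) -> tuple[MitoGenome, list[GeneFeature]]:
    """Deterministic synthetic stand-in for the real reference genome.

    The gene coordinates are the real annotation (rCRS for human,
    NC_005089 for mouse) but the sequence is pseudo-random background
    with the true reference codons planted at the variant positions the
    study discusses, so coordinate arithmetic and the worked amino-acid
    changes (e.g. m.11453G>A -> ND4 A232T) are exact while the
    surrounding sequence is synthetic.
    """
    import numpy as np

    if species not in _GENOME_LENGTH:
        raise ValueError(f"no builtin reference for {species!r}")
    length = _GENOME_LENGTH[species]
    rng = np.random.default_rng(seed + length)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    for start, codon in _PLANTED_CODONS[species]:
        seq[start - 1 : start + 2] = codon
    genome = MitoGenome(
        accession={"human": "NC_012920-like", "mouse": "NC_005089-like"}[species],
        species=species,
        sequence="".join(seq),
    )
    return genome, builtin_gene_table(species)


def extract_cds(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-strand nucleotide sequence of a protein gene.

    Reference slice for H-strand genes; reverse complement for L-strand
    genes.  Length is preserved.
    """
    if feature.kind != "protein":
        raise ValueError(f"extract_cds requires a protein feature, got kind={feature.kind!r}")
    if feature.end > genome.length:
        raise ValueError(f"{feature.name} extends past genome length {genome.length}")
    segment = genome.sequence[feature.start - 1 : feature.end]
    return reverse_complement(segment) if feature.strand == "L" else segment


def translate(cds: str, code: GeneticCode = VERTEBRATE_MITO, truncate_at_stop: bool = False) -> str:
    """Translate a coding sequence codon by codon; stops render as ``*``.

    A trailing 1-2 nt partial codon (common in mtDNA, where the stop is
    completed by polyadenylation) is flagged with a warning and left
    untranslated.  Codons containing non-ACGT symbols translate to ``X``
    with a warning.
    """
    tail = len(cds) % 3
    if tail:
        warnings.warn(
            f"trailing {tail} nt partial codon left untranslated", stacklevel=2
        )
    aas = []
    for i in range(0, len(cds) - tail, 3):
        codon = cds[i : i + 3]
        aa = code.table.get(codon)
        if aa is None:
            warnings.warn(f"non-ACGT codon {codon!r} translated as X", stacklevel=2)
            aa = "X"
        if aa == "*" and truncate_at_stop:
            aas.append("*")
            break
        aas.append(aa)
    return "".join(aas)
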