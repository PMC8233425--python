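"""Nucleotide-level mtDNA variants and their coding consequences.

A variant is located on the reference (heavy-strand) coordinate frame;
for light-strand genes the allele is complemented and the codon offset
measured from the gene end, so e.g. mouse ND6 G13997A resolves to the
P25L change on the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .reference import (
    FormatError,
    GeneFeature,
    GeneticCode,
    MitoGenome,
    VERTEBRATE_MITO,
    extract_cds,
)

__all__ = [
    "Variant",
    "CodingEffect",
    "DataError",
    "annotate_variant",
    "read_variants",
    "annotate_table",
    "is_homoplasmic",
]

_KINDS = ("substitution", "insertion", "deletion")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: heteroplasmy fraction at or above which a variant is called homoplasmic
HOMOPLASMY_THRESHOLD = 0.95


class DataError(ValueError):
    """Input data inconsistent with the reference (e.g. ref-allele mismatch)."""


@dataclass(frozen=True)
class Variant:
    """A single mtDNA change in 1-based reference coordinates.

    Insertion semantics follow mtDNA nomenclature: ``13891insC`` means a
    C inserted immediately *after* reference position 13891, represented
    as ``position=13891, ref='', alt='C', kind='insertion'``.
    """

    position: int
    ref: str
    alt: str
    kind: str
    heteroplasmy: float | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.kind == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("substitution requires single-base ref and alt")
            if self.ref == self.alt:
                raise ValueError(f"ref and alt identical ({self.ref}) at {self.position}")
        elif self.kind == "insertion" and not self.alt:
            raise ValueError("insertion requires a non-empty alt allele")
        elif self.kind == "deletion" and not self.ref:
            raise ValueError("deletion requires a non-empty ref allele")
        if self.heteroplasmy is not None and not 0.0 <= self.heteroplasmy <= 1.0:
            raise ValueError(f"heteroplasmy {self.heteroplasmy} outside [0, 1]")

    @property
    def label(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref}{self.position}{self.alt}"
        if self.kind == "insertion":
            return f"{self.position}ins{self.alt}"
        return f"{self.position}del{self.ref}"


@dataclass(frozen=True)
class CodingEffect:
    """Derived consequence of a variant: gene, codon, residue change, class."""

    gene: str | None
    codon_index: int | None
    ref_aa: str | None
    alt_aa: str | None
    effect_class: str  # synonymous | missense | nonsense | frameshift | inframe_indel | non_coding

    def __post_init__(self) -> None:
        allowed = {"synonymous", "missense", "nonsense", "frameshift", "inframe_indel", "non_coding"}
        if self.effect_class not in allowed:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


def is_homoplasmic(v: Variant, threshold: float = HOMOPLASMY_THRESHOLD) -> bool:
    """Homoplasmic when the fraction is >= threshold or unrecorded."""
    return v.heteroplasmy is None or v.heteroplasmy >= threshold


def _protein_feature_at(features: Sequence[GeneFeature], position: int) -> GeneFeature | None:
    hits = [f for f in features if f.kind == "protein" and f.contains(position)]
    if len(hits) > 1:
        warnings.warn(
            f"position {position} inside overlapping protein genes "
            f"{[f.name for f in hits]}; using {hits[0].name}",
            stacklevel=3,
        )
    return hits[0] if hits else None


def annotate_variant(
    genome: MitoGenome,
    features: Sequence[GeneFeature],
    code: GeneticCode = VERTEBRATE_MITO,
    v: Variant | None = None,
    *,
    variant: Variant | None = None,
) -> CodingEffect:
    """Resolve a variant to its coding consequence.

    Substitutions inside a protein gene are mapped onto the coding
    strand: the codon index is ``offset // 3 + 1`` where the offset runs
    from the gene start (H strand) or gene end (L strand), and L-strand
    alleles are complemented.  Indels whose length is not a multiple of
    three are frameshifts.  Variants outside protein features are
    non-coding (the containing tRNA/rRNA/control feature, if any, is
    reported as the gene).
    """
    if v is None:
        v = variant
    if v is None:
        raise TypeError("annotate_variant requires a variant")
    if v.position > genome.length:
        raise DataError(f"variant position {v.position} outside genome [1, {genome.length}]")

    feat = _protein_feature_at(features, v.position)

    if v.kind == "substitution":
        actual = genome.base(v.position)
        if actual != v.ref:
            raise DataError(
                f"ref allele mismatch at position {v.position}: variant says "
                f"{v.ref}, genome has {actual}"
            )
        if feat is None:
            return _non_coding(features, v.position)
        if feat.strand == "H":
            offset = v.position - feat.start
            ref_b, alt_b = v.ref, v.alt
        else:
            offset = feat.end - v.position
            ref_b, alt_b = v.ref.translate(_COMP), v.alt.translate(_COMP)
        codon_index = offset // 3 + 1
        pos_in_codon = offset % 3
        cds = extract_cds(genome, feat)
        codon_start = 3 * (codon_index - 1)
        codon = cds[codon_start : codon_start + 3]
        if len(codon) < 3:
            warnings.warn(
                f"{v.label} falls in the incomplete terminal codon of {feat.name}",
                stacklevel=2,
            )
            return CodingEffect(feat.name, None, None, None, "non_coding")
        assert codon[pos_in_codon] == ref_b
        alt_codon = codon[:pos_in_codon] + alt_b + codon[pos_in_codon + 1 :]
        ref_aa = code.table.get(codon, "X")
        alt_aa = code.table.get(alt_codon, "X")
        if ref_aa == alt_aa:
            klass = "synonymous"
        elif alt_aa == "*":
            klass = "nonsense"
        elif ref_aa == "*":
            warnings.warn(f"{v.label}: stop-loss reported as missense readthrough", stacklevel=2)
            klass = "missense"
        else:
            klass = "missense"
        return CodingEffect(feat.name, codon_index, ref_aa, alt_aa, klass)

    # insertions / deletions
    if v.kind == "deletion":
        span = range(v.position, v.position + len(v.ref))
        feat = next(
            (f for f in features if f.kind == "protein" and any(f.contains(p) for p in span)),
            None,
        )
        indel_len = len(v.ref)
    else:
        indel_len = len(v.alt)
    if feat is None:
        return _non_coding(features, v.position)
    klass = "frameshift" if indel_len % 3 else "inframe_indel"
    return CodingEffect(feat.name, None, None, None, klass)


def _non_coding(features: Sequence[GeneFeature], position: int) -> CodingEffect:
    other = next((f for f in features if f.kind != "protein" and f.contains(position)), None)
    return CodingEffect(other.name if other else None, None, None, None, "non_coding")


_TSV_REQUIRED = ["sample", "position", "ref", "alt", "kind"]


def read_variants(source: Union[str, IO[str]]) -> list[Variant]:
    """Read variants from a TSV or a minimal VCF.

    TSV columns: sample, position, ref, alt, kind, optional heteroplasmy
    (extra columns are ignored here and merged back by callers).  A file
    whose first non-comment line starts with ``##fileformat=VCF`` or
    whose data lines have the CHROM/POS/ID/REF/ALT shape is parsed as a
    minimal VCF (substitutions plus simple indels in VCF notation).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("##fileformat=VCF") or stripped.startswith("#CHROM"):
        return _read_vcf(text)
    return _read_tsv(text)


def _read_tsv(text: str) -> list[Variant]:
    rows = []
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in _TSV_REQUIRED if c not in header]
            if missing:
                raise FormatError(f"variant TSV missing columns {missing}")
            continue
        rec = dict(zip(header, fields))
        try:
            het = rec.get("heteroplasmy", "").strip()
            rows.append(
                Variant(
                    position=int(rec["position"]),
                    ref=rec["ref"].strip(),
                    alt=rec["alt"].strip(),
                    kind=rec["kind"].strip(),
                    heteroplasmy=float(het) if het else None,
                    sample=rec["sample"].strip(),
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"variant TSV line {lineno}: {exc}") from exc
    return rows


def _read_vcf(text: str) -> list[Variant]:
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            fields = line.split()
        if len(fields) < 5:
            raise FormatError(f"VCF line {lineno}: expected at least 5 columns")
        _chrom, pos, _vid, ref, alt = fields[:5]
        try:
            position = int(pos)
        except ValueError as exc:
            raise FormatError(f"VCF line {lineno}: bad POS {pos!r}") from exc
        ref, alt = ref.upper(), alt.upper()
        if len(ref) == 1 and len(alt) == 1:
            v = Variant(position, ref, alt, "substitution")
        elif len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
            # VCF-style insertion anchored on the preceding base
            v = Variant(position, "", alt[1:], "insertion")
        elif len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
            v = Variant(position + 1, ref[1:], "", "deletion")
        else:
            raise FormatError(f"VCF line {lineno}: unsupported allele pair {ref}>{alt}")
        out.append(v)
    return out


def annotate_table(
    genome: MitoGenome,
    features: Sequence[GeneFeature],
    variants: Iterable[Variant],
    code: GeneticCode = VERTEBRATE_MITO,
) -> pd.DataFrame:
    """Annotate a variant list into a tidy table (one row per variant)."""
    rows = []
    for v in variants:
        eff = annotate_variant(genome, features, code, v)
        rows.append(
            {
                "sample": v.sample,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "kind": v.kind,
                "heteroplasmy": v.heteroplasmy,
                "label": v.label,
                "gene": eff.gene,
                "codon_index": eff.codon_index,
                "ref_aa": eff.ref_aa,
                "alt_aa": eff.alt_aa,
                "effect_class": eff.effect_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "position",
            "ref",
            "alt",
            "kind",
            "heteroplasmy",
            "label",
            "gene",
            "codon_index",
            "ref_aa",
            "alt_aa",
            "effect_class",
        ],
    )
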