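"""Rule-based pathogenicity scoring of mtDNA coding effects.

Six criteria are evaluated per variant: Grantham distance > 50, MutPred
score > 0.7, evolutionary conservation of the original residue,
predicted conformational change, reported mitochondrial-disease
association, and mtROS overproduction.  The first two are computed or
thresholded in-package; the remainder are externally derived evidence
consumed as flags.  How the criteria combine is configurable; the
default rule,

    protein_truncating or mutpred or (grantham and conformational_change)

is the minimal rule consistent with the three adjudicated cell-line
variants (G13708A in, G11453A in, T4216C out).  Nonsense and frameshift
effects bypass the missense criteria via the protein-truncating flag.
mtROS overproduction is a cell-level measurement and is carried and
reported but not referenced by the default rule.
"""

from __future__ import annotations

import ast
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .variants import CodingEffect

__all__ = [
    "GranthamTable",
    "EvidenceRecord",
    "CriterionFlags",
    "PathogenicityCall",
    "Rule",
    "DEFAULT_RULE",
    "ConfigError",
    "grantham_distance",
    "conservation_call",
    "alignment_column",
    "evaluate_criteria",
    "classify",
]

CRITERIA = (
    "grantham",
    "mutpred",
    "conserved",
    "conformational_change",
    "disease_associated",
    "mtros_overproduction",
)

GRANTHAM_MIN = 50
MUTPRED_MIN = 0.7

_AA20 = "ARNDCQEGHILKMFPSTWYV"


class ConfigError(ValueError):
    """Invalid rule expression or threshold configuration."""


def _load_properties() -> dict[str, tuple[float, float, float]]:
    text = resources.files("mitomct.data").joinpath("grantham_properties.tsv").read_text()
    props: dict[str, tuple[float, float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        aa, c, p, v = line.split("\t")
        props[aa] = (float(c), float(p), float(v))
    if set(props) != set(_AA20):
        raise ConfigError("Grantham property table must cover the 20 standard residues")
    return props


@dataclass(frozen=True)
class GranthamTable:
    """Grantham (1974) physicochemical distances between amino-acid pairs.

    ``D(i, j) = rho * sqrt(alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2 +
    gamma*(v_i - v_j)^2)`` over composition ``c``, polarity ``p`` and
    volume ``v``, with ``rho`` normalising the mean inter-residue
    distance to 100.  Distances are rounded to integers, matching the
    published convention.
    """

    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    properties: Mapping[str, tuple[float, float, float]] = field(default_factory=_load_properties)
    rho: float = field(default=0.0)
    distances: Mapping[frozenset, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        pairs = list(itertools.combinations(sorted(self.properties), 2))
        raws = {frozenset(p): self._raw(*p) for p in pairs}
        if not self.rho:
            object.__setattr__(self, "rho", 100.0 / (sum(raws.values()) / len(raws)))
        if not self.distances:
            object.__setattr__(
                self,
                "distances",
                {k: round(self.rho * r) for k, r in raws.items()},
            )

    def _raw(self, a: str, b: str) -> float:
        c1, p1, v1 = self.properties[a]
        c2, p2, v2 = self.properties[b]
        return math.sqrt(
            self.alpha * (c1 - c2) ** 2
            + self.beta * (p1 - p2) ** 2
            + self.gamma * (v1 - v2) ** 2
        )

    def distance(self, aa1: str, aa2: str) -> int:
        for aa in (aa1, aa2):
            if aa not in self.properties:
                raise ValueError(f"{aa!r} is not a standard amino acid")
        if aa1 == aa2:
            return 0
        return self.distances[frozenset((aa1, aa2))]


_DEFAULT_TABLE: GranthamTable | None = None


def default_grantham_table() -> GranthamTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = GranthamTable()
    return _DEFAULT_TABLE


def grantham_distance(aa1: str, aa2: str, table: GranthamTable | None = None) -> int:
    """Integer Grantham distance between two standard residues."""
    return (table or default_grantham_table()).distance(aa1, aa2)


_GAPS = {"-", ".", ""}


def conservation_call(
    residues_by_species: Mapping[str, str],
    ref_species: str,
    min_identity: float = 1.0,
) -> bool | None:
    """Is the reference residue conserved across species?

    True when the fraction of species carrying the reference residue is
    at least ``min_identity`` (default: strict unanimity).  Gap
    characters are excluded; a gap-only column is indeterminate (None).
    """
    if ref_species not in residues_by_species:
        raise ValueError(f"reference species {ref_species!r} absent from the column")
    if len(residues_by_species) < 2:
        raise ValueError("conservation needs at least two species")
    informative = {s: r for s, r in residues_by_species.items() if r not in _GAPS}
    if not informative or residues_by_species[ref_species] in _GAPS:
        return None
    ref_res = informative[ref_species]
    frac = sum(1 for r in informative.values() if r == ref_res) / len(informative)
    return frac >= min_identity


def alignment_column(msa_fasta, column: int) -> dict[str, str]:
    """Extract one 1-based column of a FASTA multiple alignment as a
    species -> residue map (record ids are the species labels)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(msa_fasta, "fasta"):
        if not 1 <= column <= len(rec.seq):
            raise ValueError(f"column {column} outside alignment of width {len(rec.seq)}")
        out[rec.id] = str(rec.seq[column - 1]).upper()
    return out


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-variant criterion inputs; ``None`` means not reported.

    ``mutpred_high`` carries a qualitative above-threshold judgement for
    cases where the numeric score was not published.
    """

    grantham: int | None = None
    mutpred: float | None = None
    mutpred_high: bool | None = None
    conserved: bool | None = None
    conformational_change: bool | None = None
    disease_associated: bool | None = None
    mtros_overproduction: bool | None = None

    def __post_init__(self) -> None:
        if self.mutpred is not None and not 0.0 <= self.mutpred <= 1.0:
            raise ValueError(f"MutPred score {self.mutpred} outside [0, 1]")
        if self.grantham is not None and self.grantham < 0:
            raise ValueError("Grantham distance must be non-negative")


@dataclass(frozen=True)
class CriterionFlags:
    """Per-criterion booleans (None = evidence missing), plus the
    protein-truncating surrogate for nonsense/frameshift effects."""

    grantham: bool | None = None
    mutpred: bool | None = None
    conserved: bool | None = None
    conformational_change: bool | None = None
    disease_associated: bool | None = None
    mtros_overproduction: bool | None = None
    protein_truncating: bool = False

    def as_dict(self) -> dict[str, bool | None]:
        return {
            **{name: getattr(self, name) for name in CRITERIA},
            "protein_truncating": self.protein_truncating,
        }

    def met(self) -> list[str]:
        return [name for name in CRITERIA if getattr(self, name) is True]


@dataclass(frozen=True)
class PathogenicityCall:
    verdict: str  # predicted_pathogenic | not_predicted | indeterminate
    criteria_met: tuple[str, ...]
    rule_id: str


def evaluate_criteria(
    effect: CodingEffect,
    evidence: EvidenceRecord,
    grantham_min: float = GRANTHAM_MIN,
    mutpred_min: float = MUTPRED_MIN,
    table: GranthamTable | None = None,
) -> CriterionFlags:
    """Score one coding effect against the six criteria.

    Grantham and MutPred comparisons are strictly greater-than at the
    published thresholds (50 and 0.7).  For missense effects the
    Grantham distance is computed from the residue pair when not already
    supplied as evidence.  Missing evidence stays missing; nothing is
    invented.
    """
    if effect.effect_class not in ("missense", "nonsense", "frameshift", "synonymous", "inframe_indel"):
        raise ValueError(f"cannot score a {effect.effect_class} effect")

    truncating = effect.effect_class in ("nonsense", "frameshift")

    g: int | None = evidence.grantham
    if g is None and effect.effect_class == "missense":
        g = grantham_distance(effect.ref_aa, effect.alt_aa, table)
    grantham_flag = None if g is None else g > grantham_min

    if evidence.mutpred is not None:
        mutpred_flag: bool | None = evidence.mutpred > mutpred_min
    else:
        mutpred_flag = evidence.mutpred_high

    return CriterionFlags(
        grantham=grantham_flag,
        mutpred=mutpred_flag,
        conserved=evidence.conserved,
        conformational_change=evidence.conformational_change,
        disease_associated=evidence.disease_associated,
        mtros_overproduction=evidence.mtros_overproduction,
        protein_truncating=truncating,
    )


class Rule:
    """A boolean aggregation rule over criterion names.

    The expression uses Python's ``and``/``or``/``not`` over the six
    criterion names plus ``protein_truncating`` and is evaluated with
    Kleene three-valued logic so missing flags propagate as unknown.
    """

    def __init__(self, expression: str, rule_id: str | None = None):
        self.expression = expression
        self.rule_id = rule_id or expression
        try:
            self._tree = ast.parse(expression, mode="eval").body
        except SyntaxError as exc:
            raise ConfigError(f"invalid rule expression: {exc}") from exc
        self.names = sorted(self._collect_names(self._tree))
        known = set(CRITERIA) | {"protein_truncating"}
        unknown = set(self.names) - known
        if unknown:
            raise ConfigError(f"rule references unknown criteria: {sorted(unknown)}")

    def _collect_names(self, node: ast.AST) -> set[str]:
        if isinstance(node, ast.Name):
            return {node.id}
        if isinstance(node, ast.BoolOp):
            return set().union(*(self._collect_names(v) for v in node.values))
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            return self._collect_names(node.operand)
        raise ConfigError(f"unsupported syntax in rule expression: {ast.dump(node)}")

    def _eval(self, node: ast.AST, flags: Mapping[str, bool | None]) -> bool | None:
        if isinstance(node, ast.Name):
            return flags[node.id]
        if isinstance(node, ast.UnaryOp):
            inner = self._eval(node.operand, flags)
            return None if inner is None else not inner
        assert isinstance(node, ast.BoolOp)
        values = [self._eval(v, flags) for v in node.values]
        if isinstance(node.op, ast.Or):
            if any(v is True for v in values):
                return True
            return None if any(v is None for v in values) else False
        if any(v is False for v in values):
            return False
        return None if any(v is None for v in values) else True

    def __call__(self, flags: CriterionFlags) -> bool | None:
        return self._eval(self._tree, flags.as_dict())


DEFAULT_RULE = Rule(
    "protein_truncating or mutpred or (grantham and conformational_change)",
    rule_id="default",
)


def classify(flags: CriterionFlags, rule: Rule = DEFAULT_RULE) -> PathogenicityCall:
    """Aggregate criterion flags into a verdict under a rule.

    ``indeterminate`` is returned only when every flag the rule
    references is missing; otherwise an unsatisfied rule yields
    ``not_predicted``.
    """
    value = rule(flags)
    if value is True:
        verdict = "predicted_pathogenic"
    elif value is False:
        verdict = "not_predicted"
    else:
        # unknown: indeterminate only if every referenced *evidence* flag is
        # missing (protein_truncating is structural and always present)
        referenced = [flags.as_dict()[n] for n in rule.names if n != "protein_truncating"]
        verdict = "indeterminate" if all(v is None for v in referenced) else "not_predicted"
    return PathogenicityCall(
        verdict=verdict, criteria_met=tuple(flags.met()), rule_id=rule.rule_id
    )
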