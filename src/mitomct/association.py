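"""Cohort-level statistics: semiquantitative IHC scoring, the
mutation x MCT4 contingency test, and the exact Mann-Whitney comparison
of per-mouse metastasis counts.

The IHC grade is a five-bin ordinal of the percentage of MCT4-positive
cancer cells (-: 0, +: 1-10 %, ++: 11-50 %, +++: 51-90 %, ++++: > 90 %);
"strongly positive" means a grade of +++ or above.  The 2x2 association
between mutation status and strong positivity is tested with the
Yates-continuity-corrected chi-square on 1 df, and metastasis counts
with a tie-aware exact Mann-Whitney U (full enumeration of labelings
for n1 + n2 <= 16, normal approximation with tie correction beyond).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IHC_SCORES",
    "TissueRecord",
    "ContingencyResult",
    "MannWhitneyResult",
    "ihc_score_from_percent",
    "parse_ihc_score",
    "strong_positive",
    "chi2_yates",
    "mann_whitney_exact",
    "build_mutation_mct4_table",
    "read_cohort",
    "builtin_cohort",
]

#: ordinal IHC grades, weakest to strongest
IHC_SCORES = ("-", "+", "++", "+++", "++++")
_ORDINAL = {s: i for i, s in enumerate(IHC_SCORES)}

_STATUSES = ("none", "homoplasmy", "heteroplasmy_or_heterogeneous")

#: exact enumeration is used up to this combined sample size
EXACT_LIMIT = 16


class DataError(ValueError):
    pass


def ihc_score_from_percent(percent: float) -> str:
    """Bin a percent of positive cells into the five-grade IHC score.

    Boundaries at 10, 50 and 90 fall in the lower bin; 0 is negative.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percent {percent} outside [0, 100]")
    if percent == 0:
        return "-"
    if percent <= 10:
        return "+"
    if percent <= 50:
        return "++"
    if percent <= 90:
        return "+++"
    return "++++"


_PLUS_RUN = re.compile(r"\++")


def parse_ihc_score(text: str) -> int:
    """Resolve a printed IHC grade to its ordinal (0..4).

    Handles spacing variants ("+  +  +"), qualifiers ("++ (local)") and
    mixed entries ("- and ++++"), which resolve to the maximum
    component.
    """
    if text is None:
        raise DataError("missing IHC score")
    cleaned = str(text).replace("−", "-").replace(" ", "")
    parts = [p for p in re.split(r"and|/|,", cleaned) if p]
    ordinals = []
    for part in parts:
        plus = _PLUS_RUN.search(part)
        if plus:
            n = len(plus.group(0))
            if n > 4:
                raise DataError(f"unresolvable IHC score {text!r}")
            ordinals.append(n)
        elif part.startswith("-"):
            ordinals.append(0)
        elif part.startswith("("):
            continue  # qualifier such as "(local)"
        else:
            raise DataError(f"unresolvable IHC score {text!r}")
    if not ordinals:
        raise DataError(f"unresolvable IHC score {text!r}")
    return max(ordinals)


@dataclass(frozen=True)
class TissueRecord:
    """One cohort tissue: mutation status plus an MCT4 IHC readout."""

    id: str
    histology: str = ""
    site: str = "P"  # P = primary, M = metastasis
    mutation_status: str = "none"
    ihc_percent: float | None = None
    ihc_score: str | None = None

    def __post_init__(self) -> None:
        if self.site not in ("P", "M"):
            raise ValueError(f"{self.id}: site must be P or M")
        if self.mutation_status not in _STATUSES:
            raise ValueError(f"{self.id}: unknown mutation status {self.mutation_status!r}")
        if self.ihc_percent is None and self.ihc_score is None:
            raise ValueError(f"{self.id}: need ihc_percent or ihc_score")
        if self.ihc_percent is not None:
            if not 0 <= self.ihc_percent <= 100:
                raise ValueError(f"{self.id}: ihc_percent outside [0, 100]")
            if self.ihc_score is not None:
                derived = _ORDINAL[ihc_score_from_percent(self.ihc_percent)]
                if parse_ihc_score(self.ihc_score) != derived:
                    raise ValueError(
                        f"{self.id}: ihc_score {self.ihc_score!r} inconsistent with "
                        f"ihc_percent {self.ihc_percent}"
                    )

    @property
    def mutation_bearing(self) -> bool:
        return self.mutation_status != "none"

    def score_ordinal(self) -> int:
        if self.ihc_score is not None:
            return parse_ihc_score(self.ihc_score)
        return _ORDINAL[ihc_score_from_percent(self.ihc_percent)]


def strong_positive(record: TissueRecord, min_ordinal: int = 3) -> bool:
    """Strongly MCT4 positive: IHC grade of +++ (ordinal 3) or above."""
    return record.score_ordinal() >= min_ordinal


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple  # ((a, b), (c, d))
    chi2: float
    p: float


def chi2_yates(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Yates-continuity-corrected chi-square for a 2x2 table, 1 df.

    chi2 = N * max(0, |ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)); the
    continuity correction clamps at zero.  Any zero margin leaves the
    statistic undefined and raises.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise DataError("zero margin: chi-square statistic undefined")
    num = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2
    chi2 = num / math.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(table=((a, b), (c, d)), chi2=chi2, p=max(min(p, 1.0), 0.0))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str  # exact_enumeration | normal_approx


def _u_statistic(ranks: np.ndarray, idx: Sequence[int], n1: int) -> float:
    return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney_exact(group1: Sequence[float], group2: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with a tie-aware exact null.

    Midranks are assigned over the pooled data; for n1 + n2 <= 16 the
    p-value is the fraction of all C(n1+n2, n1) group labelings whose U
    is at least as far from the null mean n1*n2/2 as the observed U
    (ties included, so identical groups give p = 1).  Larger samples
    fall back to the normal approximation with tie correction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks, range(n1), n1)
    mu = n1 * n2 / 2

    if n1 + n2 <= EXACT_LIMIT:
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(_u_statistic(ranks, idx, n1) - mu) >= dev - 1e-9:
                hits += 1
        return MannWhitneyResult(u=u_obs, p=hits / total, n1=n1, n2=n2, method="exact_enumeration")

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values tied
        return MannWhitneyResult(u=u_obs, p=1.0, n1=n1, n2=n2, method="normal_approx")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2 * float(stats.norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u=u_obs, p=p, n1=n1, n2=n2, method="normal_approx")


def build_mutation_mct4_table(records: Iterable[TissueRecord]) -> np.ndarray:
    """2x2 counts: rows mutation-bearing / none, columns strongly
    MCT4-positive true / false.  Cell counts sum to the cohort size."""
    table = np.zeros((2, 2), dtype=int)
    for rec in records:
        row = 0 if rec.mutation_bearing else 1
        col = 0 if strong_positive(rec) else 1
        table[row, col] += 1
    return table


_COHORT_COLUMNS = {"id", "mutation_status", "ihc_score"}


def read_cohort(source: Union[str, IO[str]]) -> list[TissueRecord]:
    """Read cohort tissues from a TSV with at least id, mutation_status
    and ihc_score (or ihc_percent) columns."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    if "id" not in df.columns or "mutation_status" not in df.columns:
        raise DataError("cohort table needs id and mutation_status columns")
    records = []
    for _, row in df.iterrows():
        percent = row.get("ihc_percent", "")
        records.append(
            TissueRecord(
                id=row["id"],
                histology=row.get("histology", ""),
                site=row.get("site", "P") or "P",
                mutation_status=row["mutation_status"],
                ihc_percent=float(percent) if str(percent).strip() else None,
                ihc_score=row.get("ihc_score") or None,
            )
        )
    return records


def builtin_cohort() -> list[TissueRecord]:
    """The packaged 17-tissue NSCLC cohort (published IHC table)."""
    import io

    text = resources.files("mitomct.data").joinpath("nsclc_cohort.tsv").read_text()
    return read_cohort(io.StringIO(text))
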