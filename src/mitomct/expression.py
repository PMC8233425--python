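"""Two-condition expression contrast and pathway summarisation.

Counts are normalised within-sample to counts per million (CPM); the
contrast statistic is the difference in log2 CPM between the test and
reference conditions (logFC > 0 means higher CPM in the test
condition), and the magnitude metric is the root-square deviation (RSD)
— the square root of the squared difference, i.e. |logFC|.  Pathway
over-representation uses a one-sided Fisher exact (hypergeometric) test
at a predefined significance level of p < 0.01 with no multiple-testing
correction, against the catalogue universe; per-pathway expression
shifts are arithmetic means of member logFC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .reference import FormatError

__all__ = [
    "CountMatrix",
    "PathwayCatalog",
    "DEFAULT_PSEUDOCOUNT",
    "ENRICHMENT_ALPHA",
    "cpm",
    "log_fold_change",
    "rank_top",
    "read_gmt",
    "read_counts",
    "fisher_enrichment",
    "pathway_mean_logfc",
]

log = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
ENRICHMENT_ALPHA = 0.01


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with a reference/test condition map."""

    counts: pd.DataFrame
    conditions: Mapping[str, str]  # sample -> "ref" | "test"

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.conditions) - set(df.columns)
        if unknown:
            raise ValueError(f"condition map names unknown samples: {sorted(unknown)}")
        roles = set(self.conditions.values())
        if not roles <= {"ref", "test"}:
            raise ValueError(f"conditions must be 'ref' or 'test', got {sorted(roles)}")
        for role in ("ref", "test"):
            if role not in roles:
                raise ValueError(f"no sample assigned to the {role!r} condition")
        if (df[list(self.conditions)].sum(axis=0) == 0).any():
            raise ValueError("zero column total: cannot normalise an empty library")

    def samples(self, role: str) -> list[str]:
        return [s for s, r in self.conditions.items() if r == role]


def read_counts(source: Union[str, IO[str]], conditions: Mapping[str, str]) -> CountMatrix:
    """Read a genes x samples TSV (first column = gene symbols)."""
    df = pd.read_csv(source, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    return CountMatrix(df, dict(conditions))


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts / library size x 1e6, per sample.

    Column sums of the result equal 1e6 exactly (up to float rounding).
    """
    df = matrix.counts.astype(float)
    totals = df.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero column total")
    return df.div(totals, axis=1) * 1e6


def log_fold_change(
    matrix: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-gene contrast records: log2 CPM per condition, logFC and RSD.

    Replicate CPMs within a condition are averaged before the log, so
    any number of samples per condition is accepted.  A pseudocount
    (default 0.5 CPM) bounds the logFC for genes with zero counts.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    c = cpm(matrix)
    mean_ref = c[matrix.samples("ref")].mean(axis=1)
    mean_test = c[matrix.samples("test")].mean(axis=1)
    out = pd.DataFrame(
        {
            "gene": c.index,
            "log2cpm_ref": np.log2(mean_ref + pseudocount),
            "log2cpm_test": np.log2(mean_test + pseudocount),
        }
    ).reset_index(drop=True)
    out["logfc"] = out["log2cpm_test"] - out["log2cpm_ref"]
    out["rsd"] = np.sqrt(np.square(out["logfc"]))  # == |logfc|
    return out


def rank_top(records: pd.DataFrame, n: int, direction: str = "up") -> list[str]:
    """Top-n gene symbols by logFC (up/down) or RSD (deviation).

    Stable sort; ties break lexicographically by symbol.  ``n`` larger
    than the gene count returns every gene.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("up", "down", "deviation"):
        raise ValueError(f"unknown direction {direction!r}")
    key, ascending = {"up": ("logfc", False), "down": ("logfc", True), "deviation": ("rsd", False)}[
        direction
    ]
    ordered = records.sort_values(
        [key, "gene"], ascending=[ascending, True], kind="mergesort"
    )
    return ordered["gene"].head(n).tolist()


@dataclass
class PathwayCatalog:
    """Named gene sets over a catalogue universe."""

    pathways: dict  # id -> (name, frozenset of symbols)
    universe: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*(g for _, g in self.pathways.values())) if self.pathways else frozenset()
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid} is empty")
            if not genes <= self.universe:
                raise ValueError(f"pathway {pid} has members outside the universe")


def read_gmt(source: Union[str, IO[str]]) -> PathwayCatalog:
    """Read pathway gene sets from a GMT file (set, description, members...)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    pathways = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: need id, description and >= 1 member")
        pid, name, *members = fields
        genes = frozenset(m.strip() for m in members if m.strip())
        if not genes:
            raise FormatError(f"GMT line {lineno}: pathway {pid} has no members")
        pathways[pid] = (name, genes)
    return PathwayCatalog(pathways)


def fisher_enrichment(
    query: Iterable[str],
    catalog: PathwayCatalog,
    alpha: float = ENRICHMENT_ALPHA,
) -> pd.DataFrame:
    """One-sided over-representation test of a query set per pathway.

    For each pathway the 2x2 (in-query x in-pathway) over the catalogue
    universe gives the hypergeometric upper tail
    ``P(X >= k) = hypergeom.sf(k-1, N, K, n)``.  Query symbols outside
    the universe are dropped with a log message.  The significant set is
    {p < alpha}; no multiple-testing correction is applied.
    """
    qset = frozenset(str(g).strip() for g in query)
    dropped = qset - catalog.universe
    if dropped:
        log.info("dropping %d query symbols outside the catalogue universe", len(dropped))
    qset &= catalog.universe
    if not qset:
        log.warning("query empty after intersection with the catalogue universe")
        return pd.DataFrame(
            columns=["pathway", "name", "k", "K", "n", "N", "p", "significant"]
        )
    N = len(catalog.universe)
    n = len(qset)
    rows = []
    for pid, (name, genes) in catalog.pathways.items():
        K = len(genes)
        k = len(qset & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway": pid, "name": name, "k": k, "K": K, "n": n, "N": N,
             "p": min(p, 1.0), "significant": p < alpha}
        )
    return pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)


def pathway_mean_logfc(records: pd.DataFrame, catalog: PathwayCatalog) -> pd.DataFrame:
    """Arithmetic mean logFC over pathway members present in the records.

    Pathways with no matching symbols are reported with n_members 0 and
    a missing mean.
    """
    logfc = records.set_index("gene")["logfc"]
    rows = []
    for pid, (name, genes) in catalog.pathways.items():
        members = [g for g in genes if g in logfc.index]
        rows.append(
            {
                "pathway": pid,
                "name": name,
                "n_members": len(members),
                "mean_logfc": float(logfc.loc[members].mean()) if members else np.nan,
            }
        )
    return pd.DataFrame(rows)
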