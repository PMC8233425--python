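"""Stage orchestration behind the command-line interface.

Each ``run_*`` function composes the library modules on file inputs and
writes TSV outputs with a provenance header (tool version + config
hash).  They are deterministic given (inputs, config, seed) and are
also the programmatic entry points used by ``mitomct all``.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    DataError as AssocDataError,
    build_mutation_mct4_table,
    chi2_yates,
    read_cohort,
    strong_positive,
)
from .expression import (
    DEFAULT_PSEUDOCOUNT,
    ENRICHMENT_ALPHA,
    fisher_enrichment,
    log_fold_change,
    pathway_mean_logfc,
    rank_top,
    read_counts,
    read_gmt,
)
from .pathogenicity import (
    DEFAULT_RULE,
    GRANTHAM_MIN,
    MUTPRED_MIN,
    EvidenceRecord,
    Rule,
    classify,
    evaluate_criteria,
)
from .reference import load_gene_table, load_genome
from .variants import annotate_table, read_variants

log = logging.getLogger("mitomct")

_BOOL = {"yes": True, "true": True, "1": True, "no": False, "false": False, "0": False}


@dataclass
class PipelineConfig:
    """File paths plus the documented thresholds, all overridable."""

    genome: str | None = None
    gene_table: str | None = None
    variants: str | None = None
    evidence: str | None = None
    counts: str | None = None
    conditions: dict = field(default_factory=dict)  # sample -> ref|test
    gmt: str | None = None
    cohort: str | None = None
    out_dir: str = "."
    grantham_min: float = GRANTHAM_MIN
    mutpred_min: float = MUTPRED_MIN
    alpha: float = ENRICHMENT_ALPHA
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    homoplasmy_threshold: float = 0.95
    conservation_min_identity: float = 1.0
    rule: str | None = None  # expression; None -> default rule
    top_n: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# mitomct {__version__} config={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def _parse_bool(cell) -> bool | None:
    text = str(cell).strip().lower()
    if not text or text == "nan":
        return None
    if text in _BOOL:
        return _BOOL[text]
    raise ValueError(f"cannot interpret {cell!r} as a yes/no flag")


def _load_evidence(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def _evidence_for(row: pd.Series | None) -> EvidenceRecord:
    if row is None:
        return EvidenceRecord()
    mutpred = str(row.get("mutpred", "")).strip()
    grantham = str(row.get("grantham", "")).strip()
    return EvidenceRecord(
        grantham=int(float(grantham)) if grantham else None,
        mutpred=float(mutpred) if mutpred else None,
        mutpred_high=_parse_bool(row.get("mutpred_high", "")),
        conserved=_parse_bool(row.get("conserved", "")),
        conformational_change=_parse_bool(row.get("conformational_change", "")),
        disease_associated=_parse_bool(row.get("disease_associated", "")),
        mtros_overproduction=_parse_bool(row.get("mtros_overproduction", "")),
    )


def run_annotate(config: PipelineConfig) -> pd.DataFrame:
    """Annotate variants, score criteria and emit verdicts as one table."""
    for name in ("genome", "gene_table", "variants"):
        if getattr(config, name) is None:
            raise FileNotFoundError(f"annotate requires the {name} input")
    genome = load_genome(config.genome)
    features = load_gene_table(config.gene_table, genome_length=genome.length)
    variants = read_variants(config.variants)
    table = annotate_table(genome, features, variants)

    evidence_df = _load_evidence(config.evidence) if config.evidence else None
    rule = Rule(config.rule) if config.rule else DEFAULT_RULE

    verdicts, criteria, rule_ids = [], [], []
    for _, row in table.iterrows():
        ev_row = None
        if evidence_df is not None:
            hit = evidence_df[
                (evidence_df["sample"] == str(row["sample"]))
                & (evidence_df["position"].astype(int) == int(row["position"]))
                & (evidence_df["alt"] == str(row["alt"]))
            ]
            if len(hit):
                ev_row = hit.iloc[0]
        if row["effect_class"] in ("missense", "nonsense", "frameshift"):
            from .variants import CodingEffect

            eff = CodingEffect(
                row["gene"],
                None if pd.isna(row["codon_index"]) else int(row["codon_index"]),
                row["ref_aa"],
                row["alt_aa"],
                row["effect_class"],
            )
            flags = evaluate_criteria(
                eff,
                _evidence_for(ev_row),
                grantham_min=config.grantham_min,
                mutpred_min=config.mutpred_min,
            )
            call = classify(flags, rule)
            verdicts.append(call.verdict)
            criteria.append(",".join(call.criteria_met))
            rule_ids.append(call.rule_id)
        else:
            verdicts.append("not_applicable")
            criteria.append("")
            rule_ids.append("")
    table["verdict"] = verdicts
    table["criteria_met"] = criteria
    table["rule_id"] = rule_ids

    out = Path(config.out_dir)
    _write_tsv(table, out / "annotated_variants.tsv", config)
    counts = table["verdict"].value_counts().to_dict()
    log.info("verdict counts: %s", counts)
    return table


def run_expression(config: PipelineConfig) -> dict:
    """Per-gene contrast (sorted by RSD) plus optional pathway tables."""
    if config.counts is None:
        raise FileNotFoundError("expression requires the counts input")
    if not config.conditions:
        raise ValueError("expression requires a sample -> condition map")
    matrix = read_counts(config.counts, config.conditions)
    records = log_fold_change(matrix, pseudocount=config.pseudocount)
    ordered = records.sort_values(["rsd", "gene"], ascending=[False, True], kind="mergesort")
    out = Path(config.out_dir)
    _write_tsv(ordered, out / "expression_contrast.tsv", config)
    top_up = rank_top(records, config.top_n, "up")
    log.info("top %d upregulated: %s", config.top_n, top_up)

    result = {"records": records, "top_up": top_up, "enrichment": None, "pathway_means": None}
    if config.gmt:
        catalog = read_gmt(config.gmt)
        query = rank_top(records, config.top_n, "deviation")
        enrich = fisher_enrichment(query, catalog, alpha=config.alpha)
        means = pathway_mean_logfc(records, catalog)
        _write_tsv(enrich, out / "pathway_enrichment.tsv", config)
        _write_tsv(means, out / "pathway_mean_logfc.tsv", config)
        result["enrichment"] = enrich
        result["pathway_means"] = means
    else:
        log.info("no GMT supplied; enrichment skipped")
    return result


def run_association(config: PipelineConfig, skip_bad: bool = False) -> dict:
    """2x2 mutation x strong-MCT4 table, Yates chi-square and report."""
    if config.cohort is None:
        raise FileNotFoundError("association requires the cohort input")
    records = read_cohort(config.cohort)
    good, bad = [], []
    for rec in records:
        try:
            rec.score_ordinal()
            good.append(rec)
        except AssocDataError as exc:
            bad.append((rec.id, str(exc)))
    if bad and not skip_bad:
        raise AssocDataError(f"unresolvable IHC entries: {bad}")
    table = build_mutation_mct4_table(good)
    result = chi2_yates(table.tolist())
    out = Path(config.out_dir)
    per_tissue = pd.DataFrame(
        {
            "id": [r.id for r in good],
            "mutation_status": [r.mutation_status for r in good],
            "ihc_ordinal": [r.score_ordinal() for r in good],
            "strong_positive": [strong_positive(r) for r in good],
        }
    )
    _write_tsv(per_tissue, out / "association_per_tissue.tsv", config)
    report = io.StringIO()
    report.write(f"# mitomct {__version__} config={config.config_hash()}\n")
    report.write("mutation x strong-MCT4 2x2 (rows: mutation, none; cols: strong, not strong)\n")
    report.write(f"{table.tolist()}\n")
    report.write(f"chi2 (Yates) = {result.chi2:.4f}\np = {result.p:.6f}\n")
    out.mkdir(parents=True, exist_ok=True)
    (out / "association_report.txt").write_text(report.getvalue())
    log.info("chi2=%.4f p=%.6f", result.chi2, result.p)
    return {"table": table, "chi2": result.chi2, "p": result.p, "skipped": bad}
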