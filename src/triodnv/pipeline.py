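"""End-to-end orchestration and cohort-level yield summaries.

Two entry points exist:

* :func:`run_pipeline` — the full composition from trio VCFs (or
  in-memory trio records): de novo scan -> annotation join -> filter
  cascade -> classification -> yield summary;
* :func:`classify_table` / :func:`classify_fixture_tables` — the table
  entry point, starting from a pre-annotated variant table in the layout
  of the published pLoF and missense tables (this is how the shipped
  fixtures are exercised without genomic context).

A proband with multiple (likely) pathogenic variants counts once in
proband-level yields.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .acmg import AssignmentPolicy, Classification, TierClass, classify_variant
from .annotation import (
    Consequence,
    GeneConstraint,
    ResourceBundle,
    VariantAnnotation,
    join_annotations,
)
from .denovo_scan import detect_denovo
from .errors import DataError
from .filters import Call, CascadeResult, FilterConfig, run_cascade
from .fixtures import (
    HYPOTHESIS_DRIVEN_GENES,
    PRIOR_FAMILY_GENES,
    load_missense_table,
    load_plof_table,
)
from .geneset import GeneSet
from .trio_io import Pedigree, read_trio

LP_TIERS = (TierClass.PATHOGENIC, TierClass.LIKELY_PATHOGENIC)

_STATUS_NAMES = {"P": "persistent", "T": "transient", "A": "ambiguous"}


@dataclass
class YieldSummary:
    """Cohort-level outcome counts, stratified by stuttering status."""

    variant_counts: Counter            # TierClass -> n variants
    carriers_by_status: dict           # persistent/transient/ambiguous -> n probands
    lp_genes: frozenset[str]           # genes with a (likely) pathogenic variant
    voi_genes: frozenset[str]          # genes with a GUS variant of interest

    @property
    def n_lp_carriers(self) -> int:
        return sum(self.carriers_by_status.values())


def summarize(report: pd.DataFrame) -> YieldSummary:
    """Build the yield summary from a classification report.

    ``report`` needs columns proband, stutter_status (P/T/A), gene and
    classification (the printed tier strings).
    """
    counts = Counter(
        TierClass(v) for v in report["classification"] if v != TierClass.NOT_CLASSIFIED.value
    )
    lp_rows = report[report["classification"].isin(t.value for t in LP_TIERS)]
    carriers: dict[str, int] = {"persistent": 0, "transient": 0, "ambiguous": 0}
    for status, grp in lp_rows.groupby("stutter_status"):
        carriers[_STATUS_NAMES.get(status, status)] = grp["proband"].nunique()
    voi = report[
        report["classification"] == TierClass.VARIANT_OF_INTEREST_GUS.value
    ]
    return YieldSummary(
        variant_counts=counts,
        carriers_by_status=carriers,
        lp_genes=frozenset(lp_rows["gene"]),
        voi_genes=frozenset(voi["gene"]),
    )


def build_stuttering_gene_set(
    summary: YieldSummary,
    prior_genes: Sequence[str] = tuple(sorted(PRIOR_FAMILY_GENES)),
    excluded: Sequence[str] = tuple(sorted(HYPOTHESIS_DRIVEN_GENES)),
) -> GeneSet:
    """Union of prior family-study genes with this run's (L)P and
    variant-of-interest genes; hypothesis-driven genes stay excluded."""
    genes = (frozenset(prior_genes) | summary.lp_genes | summary.voi_genes) - frozenset(
        excluded
    )
    return GeneSet("stuttering_associated", genes)


# --------------------------------------------------------------------------
# table entry point

def _row_calls(row: Mapping) -> Optional[dict[str, Call]]:
    tools = ("mcap", "revel", "primateai", "alphamissense")
    if not all(t in row for t in tools):
        return None
    mapping = {"D": Call.D, "T": Call.T, "A": Call.A}
    return {t: mapping.get(str(row[t]).strip(), Call.MISSING) for t in tools}


def _annotation_from_row(row: Mapping) -> VariantAnnotation:
    yes = lambda v: str(v).strip().lower() in ("yes", "true", "1")
    if "variant_type" in row:  # pLoF table layout
        consequence = Consequence(str(row["variant_type"]))
        constraint = GeneConstraint(
            row["gene"], pli=float(row["pli"]), loeuf=float(row["loeuf"])
        )
    else:  # missense table layout
        consequence = Consequence.MISSENSE
        constraint = GeneConstraint(row["gene"], mis_z=float(row["mis_z"]))
    return VariantAnnotation(
        candidate=None,
        gene=str(row["gene"]),
        transcript_id=str(row.get("isoform", "")),
        consequence=consequence,
        maf=float(row["maf"]),
        constraint=constraint,
        ndd_gene=yes(row["ndd_gene"]),
        ndd_lof_mechanism=yes(row.get("ndd_lof_mechanism", "no")),
        is_major_transcript=True,       # published rows already passed the rule
        dist_to_transcript_end_bp=10_000,
        splice_canonical=consequence is Consequence.SPLICE,
        cdna_change=str(row.get("cdna_change", "")),
        protein_change=str(row.get("protein_change", "")),
        proband=str(row.get("proband", "")),
        stutter_status=str(row.get("stutter_status", "")),
    )


def classify_table(
    table: pd.DataFrame, policy: AssignmentPolicy | None = None
) -> pd.DataFrame:
    """Classify a pre-annotated variant table; returns the report frame."""
    rows = []
    for _, row in table.iterrows():
        ann = _annotation_from_row(row)
        calls = _row_calls(row)
        result = classify_variant(ann, calls, policy)
        rows.append(
            dict(
                proband=ann.proband,
                stutter_status=ann.stutter_status,
                gene=ann.gene,
                consequence=ann.consequence.value,
                criteria="-" if result.criteria is None else str(result.criteria),
                classification=result.tier.value,
            )
        )
    return pd.DataFrame(rows)


def classify_fixture_tables(
    policy: AssignmentPolicy | None = None,
) -> pd.DataFrame:
    """Classify the shipped pLoF + missense fixture tables."""
    report = pd.concat(
        [classify_table(load_plof_table(), policy),
         classify_table(load_missense_table(), policy)],
        ignore_index=True,
    )
    return report


# --------------------------------------------------------------------------
# full pipeline from trio genotypes

@dataclass
class PipelineResult:
    candidates: dict                  # trio_id -> list[DenovoCandidate]
    annotations: list[VariantAnnotation]
    cascade: CascadeResult
    report: pd.DataFrame
    summary: YieldSummary


def run_pipeline(
    trios: Mapping[str, Sequence] | Mapping[str, Sequence[str]],
    resources: ResourceBundle,
    pedigrees: Optional[Sequence[Pedigree]] = None,
    filter_config: FilterConfig | None = None,
    policy: AssignmentPolicy | None = None,
    min_depth: int = 20,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run scan -> annotate -> filter -> classify -> summarize.

    ``trios`` maps trio_id either to a list of TrioGenotypeRecord or to a
    (child, mother, father) VCF path triple (``pedigrees`` then required,
    matching by trio_id).  Deterministic: identical inputs give identical
    outputs; stage outputs are written to ``out_dir`` when given.
    """
    filter_config = filter_config or FilterConfig()
    peds = {p.trio_id: p for p in (pedigrees or [])}
    candidates = {}
    for trio_id, payload in trios.items():
        if payload and not hasattr(payload[0], "chrom"):
            if trio_id not in peds:
                raise DataError(f"no pedigree entry for trio {trio_id}")
            records = read_trio(payload, peds[trio_id], reference=resources.genome)
        else:
            records = list(payload)
        candidates[trio_id] = detect_denovo(records, trio_id, min_depth=min_depth)

    annotations = []
    for trio_id in candidates:
        annotations.extend(join_annotations(candidates[trio_id], resources))
    cascade = run_cascade(annotations, filter_config)

    rows = []
    for surv in cascade.survivors:
        ann = surv.annotation
        result = classify_variant(ann, surv.predictor_calls, policy)
        r = ann.candidate.record if ann.candidate else None
        rows.append(
            dict(
                proband=ann.proband,
                stutter_status=ann.stutter_status or "P",
                gene=ann.gene,
                chrom=r.chrom if r else "",
                pos=r.pos if r else -1,
                ref=r.ref if r else "",
                alt=r.alt if r else "",
                consequence=ann.consequence.value,
                criteria="-" if result.criteria is None else str(result.criteria),
                classification=result.tier.value,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "proband", "stutter_status", "gene", "chrom", "pos", "ref", "alt",
            "consequence", "criteria", "classification",
        ],
    )
    summary = summarize(report) if len(report) else YieldSummary(
        Counter(), {"persistent": 0, "transient": 0, "ambiguous": 0},
        frozenset(), frozenset(),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "classification_report.tsv", sep="\t", index=False)
        trace_rows = [
            dict(
                gene=t.annotation.gene, proband=t.annotation.proband,
                gate=g.gate, outcome=g.outcome.value, reason=g.reason,
            )
            for t in cascade.traces
            for g in t.results
        ]
        pd.DataFrame(trace_rows).to_csv(
            out_dir / "filter_trace.tsv", sep="\t", index=False
        )
    return PipelineResult(candidates, annotations, cascade, report, summary)
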