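"""Synthetic trio cohorts with planted de novo variants and full resources.

The generator emulates the study's inputs without any external download:
a small artificial genome carrying multi-exon transcript models, trio
VCFs (child/mother/father, gVCF-style with explicit parental
homozygous-reference calls) containing Mendelian background variation
plus planted de novo variants, and the annotation resource bundle
(constraint metrics, allele frequencies, predictor scores, exon
expression, protein domains).

Every planted variant comes from a scenario template that straddles one
specific pipeline gate — below-threshold constraint decoys, synonymous
changes, secondary-findings genes, near-stop pLoF with and without a
rescuing domain, canonical and non-canonical splice positions, low
coverage, stray parental reads — and the generator records each
variant's intended detection, cascade and classification outcome in a
truth table.  All randomness flows from ``SimulationConfig.seed``; a
fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneConstraint,
    PredictorScores,
    ResourceBundle,
    TranscriptModel,
)
from .errors import ConfigurationError
from .trio_io import Pedigree, TrioGenotypeRecord, write_trio

CHROM = "1"
_BASES = np.array(list("ACGT"))

# transcript layout shared by all synthetic genes (gene-relative, 0-based)
_EXONS = ((0, 150), (270, 480), (600, 753))
_CDNA_LEN = 513
_UTR5 = 30            # cDNA bases before the CDS
_N_CODONS = 160       # incl. the stop codon
_GENE_STEP = 2000
_BACKGROUND_LO = 25_000
_GENOME_LEN = 72_000

# scores above / below the published damaging cutoffs
_SCORES_ALL_D = dict(mcap=0.03, revel=0.6, primateai=0.85, alphamissense=0.7)
_SCORES_ONE_D = dict(mcap=0.03, revel=0.3, primateai=0.5, alphamissense=0.2)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_trios: int = 4
    sites_per_trio: int = 150
    n_planted_per_trio: int = 4
    depth_mean: float = 60.0
    min_depth: int = 20          # coverage rule the truth table assumes
    low_child_depth: int = 15    # depth used by the below-coverage decoy
    expression_fpkm: float = 5.0
    low_expression_fpkm: float = 0.1

    def __post_init__(self):
        if self.n_planted_per_trio > self.sites_per_trio:
            raise ConfigurationError("more planted variants than sites per trio")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")


@dataclass(frozen=True)
class _GeneSpec:
    name: str
    strand: str
    pli: float
    loeuf: float
    mis_z: float
    ndd: bool = False
    ndd_lof: bool = False
    major: bool = True
    domain: Optional[tuple[int, int]] = None  # cDNA interval


_GENES = (
    _GeneSpec("SIMG1", "+", 0.99, 0.10, 3.5, ndd=True, ndd_lof=True),
    _GeneSpec("SIMG2", "-", 0.98, 0.15, 3.6, ndd=True),
    _GeneSpec("SIMG3", "+", 0.97, 0.20, 1.0),
    _GeneSpec("SIMG4", "-", 0.95, 0.25, 3.2, ndd=True),
    _GeneSpec("SIMG5", "+", 0.89, 0.61, 2.4),                    # just-below decoy
    _GeneSpec("TP53", "+", 0.95, 0.30, 3.0),                     # ACMG SF gene
    _GeneSpec("SIMG7", "+", 0.96, 0.22, 1.5),
    _GeneSpec("SIMG8", "+", 0.94, 0.18, 1.2, ndd=True, ndd_lof=True,
              domain=("KINASE", 460, 510)),
    _GeneSpec("SIMG9", "+", 0.95, 0.21, 1.1),
    _GeneSpec("SIMG10", "+", 0.99, 0.12, 3.3, ndd=True, ndd_lof=True),
    _GeneSpec("SIMG11", "+", 0.98, 0.14, 3.1, major=False),
)


@dataclass(frozen=True)
class _Template:
    """One planted-variant scenario with its intended pipeline outcome."""

    name: str
    gene: str
    kind: str               # snv_stop | snv_missense | snv_syn | del_fs | splice_snv
    codon: int = 0          # for CDS SNVs
    intron_offset: int = 0  # for splice_snv: bases into the first intron
    scores: Optional[dict] = None
    maf: float = 0.0
    child_dp: Optional[int] = None
    parent_alt_reads: int = 0
    expect_detected: bool = True
    expect_survivor: bool = False
    decisive_gate: str = ""
    expected_criteria: str = ""
    expected_class: str = ""


_TEMPLATES = (
    _Template("pathogenic_stop", "SIMG1", "snv_stop", codon=40,
              expect_survivor=True, expected_criteria="PVS1, PS2, PM2",
              expected_class="Pathogenic"),
    _Template("lp_missense", "SIMG2", "snv_missense", codon=45,
              scores=_SCORES_ALL_D, expect_survivor=True,
              expected_criteria="PS2, PM2, PP2, PP3",
              expected_class="Likely pathogenic"),
    _Template("voi_stop", "SIMG3", "snv_stop", codon=50, expect_survivor=True,
              expected_class="Variant of interest in GUS"),
    _Template("vus_missense", "SIMG4", "snv_missense", codon=48,
              scores=_SCORES_ONE_D, expect_survivor=True,
              expected_criteria="PS2, PM2, PP2, BP4", expected_class="VUS"),
    _Template("lp_missense_seen_once", "SIMG2", "snv_missense", codon=60,
              scores=_SCORES_ALL_D, maf=3.2e-5, expect_survivor=True,
              expected_criteria="PS2, PP2, PP3",
              expected_class="Likely pathogenic"),
    _Template("constraint_decoy", "SIMG5", "snv_stop", codon=40,
              decisive_gate="constraint"),
    _Template("synonymous_decoy", "SIMG1", "snv_syn", codon=70,
              decisive_gate="nonsynonymous"),
    _Template("sf_gene_decoy", "TP53", "snv_missense", codon=33,
              scores=_SCORES_ALL_D, decisive_gate="acmg_sf"),
    _Template("near_end_decoy", "SIMG7", "snv_stop", codon=149,
              decisive_gate="plof_position"),
    _Template("near_end_in_domain", "SIMG8", "snv_stop", codon=144,
              expect_survivor=True, expected_criteria="PVS1, PS2, PM2",
              expected_class="Pathogenic"),
    _Template("splice_canonical", "SIMG9", "splice_snv", intron_offset=1,
              expect_survivor=True,
              expected_class="Variant of interest in GUS"),
    _Template("splice_noncanonical_decoy", "SIMG9", "splice_snv", intron_offset=5,
              decisive_gate="nonsynonymous"),
    _Template("low_depth_decoy", "SIMG1", "snv_missense", codon=90,
              scores=_SCORES_ALL_D, child_dp=15, expect_detected=False),
    _Template("parent_reads_decoy", "SIMG1", "snv_missense", codon=95,
              scores=_SCORES_ALL_D, parent_alt_reads=2, expect_detected=False),
    _Template("frameshift_pathogenic", "SIMG10", "del_fs", codon=80,
              expect_survivor=True, expected_criteria="PVS1, PS2, PM2",
              expected_class="Pathogenic"),
    _Template("nonmajor_decoy", "SIMG11", "snv_stop", codon=40,
              decisive_gate="plof_position"),
)


# --------------------------------------------------------------------------
# genome & transcript construction

def _gene_offset(index: int) -> int:
    return 1000 + index * _GENE_STEP


def _build_transcript(spec: _GeneSpec, index: int, config: SimulationConfig):
    o = _gene_offset(index)
    exons = tuple((o + s, o + e) for s, e in _EXONS)
    # provisional model (CDS = full span) just for coordinate mapping
    prov = TranscriptModel(
        transcript_id=f"NMSIM_{index:04d}", gene=spec.name, chrom=CHROM,
        strand=spec.strand, exons=exons, cds_start=exons[0][0], cds_end=exons[-1][1],
    )
    g_first = prov.cdna_to_genomic(_UTR5)
    g_last = prov.cdna_to_genomic(_UTR5 + _N_CODONS * 3 - 1)
    fpkm = config.expression_fpkm if spec.major else config.low_expression_fpkm
    expr = {
        "fetal_cortex": tuple([fpkm] * len(exons)),
        "adult_cortex": tuple([fpkm] * len(exons)),
    }
    return TranscriptModel(
        transcript_id=prov.transcript_id, gene=spec.name, chrom=CHROM,
        strand=spec.strand, exons=exons,
        cds_start=min(g_first, g_last), cds_end=max(g_first, g_last) + 1,
        domains=(() if spec.domain is None else ((spec.domain[0], spec.domain[1], spec.domain[2]),)),
        exon_expression=expr,
    )


_COMP = str.maketrans("ACGT", "TGCA")


def _set_cdna_base(genome: list[str], tm: TranscriptModel, cdna_idx: int, base: str):
    g = tm.cdna_to_genomic(cdna_idx)
    genome[g] = base if tm.strand == "+" else base.translate(_COMP)


def _plant_codon(genome: list[str], tm: TranscriptModel, codon: int, bases: str):
    for k, b in enumerate(bases):
        _set_cdna_base(genome, tm, _UTR5 + 3 * codon + k, b)


@dataclass
class _PlantedVariant:
    template: _Template
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str


def _build_world(config: SimulationConfig):
    """Genome, transcripts and the genomic form of every template variant."""
    rng = np.random.default_rng(config.seed)
    genome = list(rng.choice(_BASES, size=_GENOME_LEN))
    transcripts = {
        spec.name: _build_transcript(spec, i, config) for i, spec in enumerate(_GENES)
    }
    for tm in transcripts.values():
        _plant_codon(genome, tm, _N_CODONS - 1, "TAA")  # translation stop

    planted: dict[str, _PlantedVariant] = {}
    for t in _TEMPLATES:
        tm = transcripts[t.gene]
        if t.kind in ("snv_stop", "snv_missense", "snv_syn"):
            ref_codon, within, alt_base, cons = {
                "snv_stop": ("TGG", 2, "A", "stop_gain"),        # TGG -> TGA
                "snv_missense": ("GCT", 1, "T", "missense"),     # GCT -> GTT
                "snv_syn": ("CTG", 2, "A", "synonymous"),        # CTG -> CTA
            }[t.kind]
            _plant_codon(genome, tm, t.codon, ref_codon)
            cdna = _UTR5 + 3 * t.codon + within
            g = tm.cdna_to_genomic(cdna)
            ref_g = ref_codon[within] if tm.strand == "+" else ref_codon[within].translate(_COMP)
            alt_g = alt_base if tm.strand == "+" else alt_base.translate(_COMP)
            planted[t.name] = _PlantedVariant(t, g + 1, ref_g, alt_g, cons)
        elif t.kind == "del_fs":
            # 1-bp deletion mid-CDS on a plus-strand gene; surrounding bases
            # are forced distinct so the representation is already minimal
            assert tm.strand == "+"
            g = tm.cdna_to_genomic(_UTR5 + 3 * t.codon)
            genome[g - 1], genome[g], genome[g + 1] = "A", "C", "G"
            planted[t.name] = _PlantedVariant(
                t, g, genome[g - 1] + genome[g], genome[g - 1], "frameshift"
            )
        elif t.kind == "splice_snv":
            assert tm.strand == "+"
            donor = tm.exons[0][1]  # first intronic base after exon 1
            genome[donor], genome[donor + 1] = "G", "T"  # canonical GT donor
            g = donor + t.intron_offset - 1
            ref_g = genome[g]
            alt_g = "C" if ref_g != "C" else "A"
            cons = "splice" if t.intron_offset <= 2 else "other"
            planted[t.name] = _PlantedVariant(t, g + 1, ref_g, alt_g, cons)
        else:
            raise AssertionError(t.kind)
    return "".join(genome), transcripts, planted


def generate_resources(config: SimulationConfig) -> ResourceBundle:
    """Annotation resource bundle consistent with the scenario templates."""
    genome, transcripts, planted = _build_world(config)
    constraint = {
        s.name: GeneConstraint(s.name, pli=s.pli, loeuf=s.loeuf, mis_z=s.mis_z)
        for s in _GENES
    }
    maf = {}
    scores = {}
    for pv in planted.values():
        key = (CHROM, pv.pos, pv.ref, pv.alt)
        if pv.template.maf:
            maf[key] = pv.template.maf
        if pv.template.scores is not None:
            scores[key] = PredictorScores(**pv.template.scores, gerp=5.0, consurf=8)
    return ResourceBundle(
        constraint=constraint,
        transcripts=tuple(transcripts.values()),
        genome={CHROM: genome},
        maf=maf,
        predictor_scores=scores,
        ndd_genes=frozenset(s.name for s in _GENES if s.ndd),
        ndd_lof_genes=frozenset(s.name for s in _GENES if s.ndd_lof),
    )


# --------------------------------------------------------------------------
# trio genotype generation

def _depth(rng, config: SimulationConfig, floor: int) -> int:
    return max(floor, int(rng.poisson(config.depth_mean)))


def _planted_record(pv: _PlantedVariant, rng, config: SimulationConfig):
    t = pv.template
    child_dp = t.child_dp if t.child_dp is not None else _depth(rng, config, config.min_depth)
    mother_dp = _depth(rng, config, config.min_depth)
    father_dp = _depth(rng, config, config.min_depth)
    alt_reads = max(1, int(rng.binomial(child_dp, 0.5)))
    return TrioGenotypeRecord(
        CHROM, pv.pos, pv.ref, pv.alt,
        child_gt=(0, 1), mother_gt=(0, 0), father_gt=(0, 0),
        child_dp=child_dp, mother_dp=mother_dp, father_dp=father_dp,
        child_alt_reads=min(alt_reads, child_dp),
        mother_alt_reads=0,
        father_alt_reads=min(t.parent_alt_reads, father_dp),
    )


def _background_records(rng, config: SimulationConfig, genome: str, n: int):
    """Mendelian (inherited) variant sites: never de novo by construction."""
    positions = rng.choice(
        np.arange(_BACKGROUND_LO, _GENOME_LEN - 1), size=n, replace=False
    )
    records = []
    for pos0 in sorted(int(p) for p in positions):
        ref = genome[pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        father = [(0, 1), (1, 1), (0, 0)][rng.choice(3, p=[0.5, 0.2, 0.3])]
        mother = (0, 0) if father != (0, 0) else (0, 1)
        child = (int(rng.choice(father)), int(rng.choice(mother)))
        dps = [_depth(rng, config, 1) for _ in range(3)]
        gts = {"child": child, "mother": mother, "father": father}
        ars = {
            who: int(rng.binomial(dp, 0.5)) if 1 in gt else 0
            for (who, gt), dp in zip(gts.items(), dps)
        }
        records.append(
            TrioGenotypeRecord(
                CHROM, pos0 + 1, ref, alt,
                child_gt=child, mother_gt=mother, father_gt=father,
                child_dp=dps[0], mother_dp=dps[1], father_dp=dps[2],
                child_alt_reads=min(ars["child"], dps[0]),
                mother_alt_reads=min(ars["mother"], dps[1]),
                father_alt_reads=min(ars["father"], dps[2]),
            )
        )
    return records


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    pedigrees: list[Pedigree]
    records_by_trio: dict[str, list[TrioGenotypeRecord]]
    resources: ResourceBundle
    truth: pd.DataFrame
    vcf_paths: dict[str, tuple[Path, Path, Path]] = field(default_factory=dict)


def generate_trio(
    config: SimulationConfig, trio_index: int = 0
) -> tuple[Pedigree, list[TrioGenotypeRecord], pd.DataFrame]:
    """Generate one trio's genotype records and its planted-variant truth."""
    resources = generate_resources(config)
    genome = resources.genome[CHROM]
    _, _, planted = _build_world(config)
    rng = np.random.default_rng((config.seed, 1, trio_index))
    trio_id = f"SYNTRIO_{trio_index + 1}"
    ped = Pedigree(trio_id, f"{trio_id}_c", f"{trio_id}_m", f"{trio_id}_f")

    slots = [
        _TEMPLATES[(trio_index * config.n_planted_per_trio + k) % len(_TEMPLATES)]
        for k in range(config.n_planted_per_trio)
    ]
    # avoid planting the same template twice in one trio
    seen, templates = set(), []
    for t in slots:
        if t.name not in seen:
            templates.append(t)
            seen.add(t.name)

    records, truth_rows = [], []
    for t in templates:
        pv = planted[t.name]
        records.append(_planted_record(pv, rng, config))
        truth_rows.append(
            dict(
                trio_id=trio_id, template=t.name, gene=t.gene, chrom=CHROM,
                pos=pv.pos, ref=pv.ref, alt=pv.alt, consequence=pv.consequence,
                expect_detected=t.expect_detected,
                expect_survivor=t.expect_survivor,
                decisive_gate=t.decisive_gate,
                expected_criteria=t.expected_criteria,
                expected_class=t.expected_class,
            )
        )
    n_bg = config.sites_per_trio - len(records)
    records.extend(_background_records(rng, config, genome, n_bg))
    # one site with a missing paternal genotype: excluded by the scanner
    missing_pos0 = _BACKGROUND_LO - 100 - trio_index
    records.append(
        TrioGenotypeRecord(
            CHROM, missing_pos0 + 1, genome[missing_pos0],
            "A" if genome[missing_pos0] != "A" else "G",
            child_gt=(0, 1), mother_gt=(0, 0), father_gt=None,
            child_dp=40, mother_dp=40, father_dp=0,
            child_alt_reads=20,
        )
    )
    records.sort(key=lambda r: (r.pos, r.ref, r.alt))
    return ped, records, pd.DataFrame(truth_rows)


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate the full synthetic cohort; optionally write trio VCFs."""
    resources = generate_resources(config)
    pedigrees, records_by_trio, truths = [], {}, []
    for i in range(config.n_trios):
        ped, records, truth = generate_trio(config, i)
        pedigrees.append(ped)
        records_by_trio[ped.trio_id] = records
        truths.append(truth)
    bundle = SyntheticBundle(
        config=config,
        pedigrees=pedigrees,
        records_by_trio=records_by_trio,
        resources=resources,
        truth=pd.concat(truths, ignore_index=True),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for ped in pedigrees:
            bundle.vcf_paths[ped.trio_id] = write_trio(
                records_by_trio[ped.trio_id], ped, out_dir
            )
        bundle.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        with open(out_dir / "pedigree.tsv", "w") as fh:
            fh.write("trio_id\tchild\tmother\tfather\tcohort\n")
            for ped in pedigrees:
                fh.write(
                    f"{ped.trio_id}\t{ped.child_id}\t{ped.mother_id}\t"
                    f"{ped.father_id}\t{ped.cohort}\n"
                )
    return bundle
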