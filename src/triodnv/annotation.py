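"""Annotation of de novo candidates against gene-level resources.

This module joins candidates to resource tables (gene constraint,
population allele frequency, missense predictor scores, transcript
models with per-exon brain expression and protein domains) and computes
the transcript-level features the downstream filter cascade needs:
consequence class, major-transcript status, cDNA distance to the
translation stop and canonical splice-site status.

One transcript per gene is designated in the resources; no
transcript-picking heuristic is applied.  "End of the transcript" is
interpreted as the translation stop in cDNA coordinates, because the
50-bp end rule exists to capture loss-of-function variants likely to
escape nonsense-mediated decay.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .denovo_scan import DenovoCandidate
from .errors import ConfigurationError, DataError

# flag vocabulary used in VariantAnnotation.flags
FLAG_UNSCORED = "UNSCORED"            # gene missing from the constraint table
FLAG_NO_TRANSCRIPT = "NO_TRANSCRIPT"  # no transcript model covers the site
FLAG_MISSING_EXPRESSION = "MISSING_EXPRESSION"
FLAG_PAST_STOP = "PAST_STOP"          # variant downstream of the stop codon


class Consequence(enum.Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: probable loss-of-function consequence classes
PLOF_CLASSES = frozenset(
    {Consequence.STOP_GAIN, Consequence.STOP_LOSS,
     Consequence.FRAMESHIFT, Consequence.SPLICE}
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneConstraint:
    """gnomAD-style per-gene intolerance metrics."""

    gene: str
    pli: Optional[float] = None     # P(loss-of-function intolerant), in [0,1]
    loeuf: Optional[float] = None   # LoF observed/expected upper bound, >= 0
    mis_z: Optional[float] = None   # missense depletion z-score

    def __post_init__(self):
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise DataError(f"{self.gene}: pLI must be in [0,1], got {self.pli}")
        if self.loeuf is not None and self.loeuf < 0:
            raise DataError(f"{self.gene}: LOEUF must be >= 0, got {self.loeuf}")


@dataclass(frozen=True)
class PredictorScores:
    """Missense pathogenicity and conservation scores for one variant."""

    mcap: Optional[float] = None
    revel: Optional[float] = None
    primateai: Optional[float] = None
    alphamissense: Optional[float] = None
    gerp: Optional[float] = None
    consurf: Optional[int] = None  # 1 (variable) .. 9 (conserved)

    def __post_init__(self):
        if self.consurf is not None and self.consurf not in range(1, 10):
            raise DataError(f"ConSurf grade must be in 1..9, got {self.consurf}")


@dataclass(frozen=True)
class TranscriptModel:
    """A single transcript: exon structure, CDS, domains, exon expression.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order, non-overlapping.  ``cds_start``/``cds_end`` delimit the coding
    region (half-open, genomic); both boundaries must fall inside exons.
    ``domains`` are (name, cdna_start, cdna_end) half-open intervals in
    transcript cDNA coordinates.  ``exon_expression`` maps a tissue
    context to one FPKM-like value per exon, in transcript order.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    domains: tuple[tuple[str, int, int], ...] = ()
    exon_expression: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in "+-":
            raise DataError(f"{self.transcript_id}: strand must be + or -")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise DataError(
                    f"{self.transcript_id}: exons must be sorted, non-overlapping"
                )
            prev_end = e
        if not (self._in_exon(self.cds_start) and self._in_exon(self.cds_end - 1)):
            raise DataError(f"{self.transcript_id}: CDS boundaries outside exons")
        for ctx, vals in self.exon_expression.items():
            if len(vals) != len(self.exons):
                raise DataError(
                    f"{self.transcript_id}: expression vector for {ctx} has "
                    f"{len(vals)} values for {len(self.exons)} exons"
                )

    # -- coordinate machinery -------------------------------------------

    def _in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cdna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_cdna(self, pos0: int) -> Optional[int]:
        """cDNA index of a genomic position, or None if intronic/outside."""
        cum = 0
        idx_plus = None
        for s, e in self.exons:
            if s <= pos0 < e:
                idx_plus = cum + (pos0 - s)
                break
            cum += e - s
        if idx_plus is None:
            return None
        return idx_plus if self.strand == "+" else self.cdna_length - 1 - idx_plus

    def cdna_to_genomic(self, idx: int) -> int:
        if not (0 <= idx < self.cdna_length):
            raise DataError(f"cDNA index {idx} out of range")
        idx_plus = idx if self.strand == "+" else self.cdna_length - 1 - idx
        cum = 0
        for s, e in self.exons:
            if idx_plus < cum + (e - s):
                return s + (idx_plus - cum)
            cum += e - s
        raise AssertionError("unreachable")

    def exon_index(self, pos0: int) -> Optional[int]:
        """Transcript-order exon index containing a genomic position."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos0 < e:
                return i if self.strand == "+" else self.n_exons - 1 - i
        return None

    def intron_offset(self, pos0: int) -> Optional[int]:
        """Distance (>=1) from an intronic position to the nearest exon edge."""
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 <= pos0 < s2:
                return min(pos0 - e1 + 1, s2 - pos0)
        return None

    def nearest_exonic_cdna(self, pos0: int) -> int:
        """cDNA index of the exon base closest to a position (intron-safe)."""
        c = self.genomic_to_cdna(pos0)
        if c is not None:
            return c
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 <= pos0 < s2:
                left, right = e1 - 1, s2
                g = left if (pos0 - left) <= (right - pos0) else right
                c = self.genomic_to_cdna(g)
                assert c is not None
                return c
        raise DataError(f"position {pos0 + 1} outside transcript {self.transcript_id}")

    # -- sequence machinery ---------------------------------------------

    def spliced_cdna(self, genome: Mapping[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return seq if self.strand == "+" else _revcomp(seq)

    def cds_cdna_span(self) -> tuple[int, int]:
        """Half-open cDNA interval of the coding sequence (incl. stop codon)."""
        a = self.genomic_to_cdna(self.cds_start)
        b = self.genomic_to_cdna(self.cds_end - 1)
        if a is None or b is None:
            raise DataError(f"{self.transcript_id}: CDS boundary not exonic")
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        lo, hi = self.cds_cdna_span()
        return self.spliced_cdna(genome)[lo:hi]


def classify_consequence(
    pos: int,
    ref: str,
    alt: str,
    transcript: TranscriptModel,
    genome: Mapping[str, str],
) -> Consequence:
    """Deterministic consequence call for a variant on one transcript.

    SNVs in the CDS are classified by codon translation; intronic SNVs at
    positions +/-1 or +/-2 of an exon boundary are ``splice`` (the main
    donor/acceptor sites) and deeper intronic positions are ``other``;
    coding indels whose length change is not a multiple of three are
    ``frameshift`` (in-frame indels fall into ``other``).
    """
    pos0 = pos - 1
    if not (transcript.tx_start <= pos0 < transcript.tx_end):
        raise DataError(
            f"variant {transcript.chrom}:{pos} outside transcript "
            f"{transcript.transcript_id}"
        )
    if len(ref) == 1 and len(alt) == 1:
        cdna = transcript.genomic_to_cdna(pos0)
        if cdna is None:
            off = transcript.intron_offset(pos0)
            return Consequence.SPLICE if off is not None and off <= 2 else Consequence.OTHER
        lo, hi = transcript.cds_cdna_span()
        if not (lo <= cdna < hi):
            return Consequence.OTHER  # UTR
        cds_off = cdna - lo
        codon_i, within = divmod(cds_off, 3)
        cds = transcript.cds_sequence(genome)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            return Consequence.OTHER  # trailing partial codon
        ref_b = ref if transcript.strand == "+" else _revcomp(ref)
        alt_b = alt if transcript.strand == "+" else _revcomp(alt)
        if codon[within] != ref_b:
            raise DataError(
                f"reference mismatch at {transcript.chrom}:{pos} "
                f"({transcript.transcript_id}): expected {codon[within]}, got {ref_b}"
            )
        alt_codon = codon[:within] + alt_b + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            return Consequence.SYNONYMOUS
        if aa_alt == "*":
            return Consequence.STOP_GAIN
        if aa_ref == "*":
            return Consequence.STOP_LOSS
        return Consequence.MISSENSE
    # indel: the first REF base is the VCF anchor; the event starts after it
    event_lo = pos0 + 1
    event_hi = max(pos0 + len(ref), event_lo + 1)
    in_cds = any(
        max(s, transcript.cds_start, event_lo)
        < min(e, transcript.cds_end, event_hi)
        for s, e in transcript.exons
    )
    if in_cds:
        if abs(len(ref) - len(alt)) % 3 != 0:
            return Consequence.FRAMESHIFT
        return Consequence.OTHER  # in-frame indel
    off = transcript.intron_offset(event_lo)
    return Consequence.SPLICE if off is not None and off <= 2 else Consequence.OTHER


def is_major_transcript(
    transcript: TranscriptModel,
    exon_index: int,
    expression_floor: float = 1.0,
) -> tuple[bool, Optional[str]]:
    """True iff the exon is expressed (>= floor) in at least one brain context.

    Returns ``(value, flag)``; flag is MISSING_EXPRESSION when no
    expression data is available, in which case the value is False.
    """
    if not (0 <= exon_index < transcript.n_exons):
        raise DataError(
            f"exon index {exon_index} out of range for {transcript.transcript_id}"
        )
    if not transcript.exon_expression:
        return False, FLAG_MISSING_EXPRESSION
    for vals in transcript.exon_expression.values():
        if vals[exon_index] >= expression_floor:
            return True, None
    return False, None


def dist_to_transcript_end(
    pos: int, transcript: TranscriptModel
) -> tuple[int, Optional[str]]:
    """cDNA distance (bases) from the variant to the translation stop.

    A variant at the stop codon gives 0; positions downstream of the stop
    give 0 with a PAST_STOP flag.  Intronic positions use the nearest
    exonic base.
    """
    pos0 = pos - 1
    cdna = transcript.nearest_exonic_cdna(pos0)
    lo, hi = transcript.cds_cdna_span()
    stop_start = hi - 3
    if cdna >= hi:
        return 0, FLAG_PAST_STOP
    return max(0, stop_start - cdna), None


# --------------------------------------------------------------------------
# resource bundle and the join

@dataclass
class ResourceBundle:
    """All annotation resources, indexed for the join.

    maf and predictor scores are keyed by (chrom, pos, ref, alt); genes
    absent from ``maf`` are treated as absent from the population
    reference (MAF 0).
    """

    constraint: Mapping[str, GeneConstraint]
    transcripts: Sequence[TranscriptModel]
    genome: Mapping[str, str]
    maf: Mapping[tuple[str, int, str, str], float] = field(default_factory=dict)
    predictor_scores: Mapping[tuple[str, int, str, str], PredictorScores] = field(
        default_factory=dict
    )
    ndd_genes: frozenset[str] = frozenset()
    ndd_lof_genes: frozenset[str] = frozenset()  # NDD genes with a LoF mechanism

    def transcript_for(self, chrom: str, pos: int) -> Optional[TranscriptModel]:
        pos0 = pos - 1
        for tm in self.transcripts:
            if tm.chrom == chrom and tm.tx_start <= pos0 < tm.tx_end:
                return tm
        return None


@dataclass(frozen=True)
class VariantAnnotation:
    """A de novo candidate joined to all resources; unit of filtering."""

    candidate: Optional[DenovoCandidate]
    gene: Optional[str]
    transcript_id: Optional[str]
    consequence: Consequence
    maf: float = 0.0
    constraint: Optional[GeneConstraint] = None
    scores: Optional[PredictorScores] = None
    ndd_gene: bool = False
    ndd_lof_mechanism: bool = False
    is_major_transcript: bool = True
    dist_to_transcript_end_bp: int = 0
    in_functional_domain: bool = False
    splice_canonical: bool = False
    cdna_change: str = ""
    protein_change: str = ""
    proband: str = ""
    stutter_status: str = ""  # P | T | A, when phenotype data is joined
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.maf < 0:
            raise DataError(f"MAF must be >= 0, got {self.maf}")

    @property
    def is_plof(self) -> bool:
        return self.consequence in PLOF_CLASSES


def join_annotations(
    candidates: Sequence[DenovoCandidate],
    resources: ResourceBundle,
    expression_floor: float = 1.0,
) -> list[VariantAnnotation]:
    """Join every candidate to its resources; total (|out| = |in|).

    Candidates with no covering transcript or no constraint row are
    flagged (NO_TRANSCRIPT / UNSCORED), never dropped.
    """
    out = []
    for cand in candidates:
        r = cand.record
        flags: set[str] = set()
        tm = resources.transcript_for(r.chrom, r.pos)
        if tm is None:
            out.append(
                VariantAnnotation(
                    candidate=cand, gene=None, transcript_id=None,
                    consequence=Consequence.OTHER,
                    maf=resources.maf.get(r.key, 0.0),
                    proband=cand.trio_id,
                    flags=frozenset({FLAG_NO_TRANSCRIPT}),
                )
            )
            continue
        consequence = classify_consequence(r.pos, r.ref, r.alt, tm, resources.genome)
        constraint = resources.constraint.get(tm.gene)
        if constraint is None:
            flags.add(FLAG_UNSCORED)
        pos0 = r.pos - 1
        exon_i = tm.exon_index(pos0)
        if exon_i is None:
            # intronic (splice) variants inherit the adjacent exon
            exon_i = tm.exon_index(tm.cdna_to_genomic(tm.nearest_exonic_cdna(pos0)))
        assert exon_i is not None
        major, mflag = is_major_transcript(tm, exon_i, expression_floor)
        if mflag:
            flags.add(mflag)
        dist, dflag = dist_to_transcript_end(r.pos, tm)
        if dflag:
            flags.add(dflag)
        cdna = tm.nearest_exonic_cdna(pos0)
        in_domain = any(s <= cdna < e for _, s, e in tm.domains)
        off = tm.intron_offset(pos0)
        out.append(
            VariantAnnotation(
                candidate=cand,
                gene=tm.gene,
                transcript_id=tm.transcript_id,
                consequence=consequence,
                maf=resources.maf.get(r.key, 0.0),
                constraint=constraint,
                scores=resources.predictor_scores.get(r.key),
                ndd_gene=tm.gene in resources.ndd_genes,
                ndd_lof_mechanism=tm.gene in resources.ndd_lof_genes,
                is_major_transcript=major,
                dist_to_transcript_end_bp=dist,
                in_functional_domain=in_domain,
                splice_canonical=off is not None and off <= 2,
                proband=cand.trio_id,
                flags=frozenset(flags),
            )
        )
    return out
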