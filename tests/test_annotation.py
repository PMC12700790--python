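"""Consequence calling, transcript coordinates and the annotation join."""

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from triodnv.annotation import (
    FLAG_UNSCORED,
    Consequence,
    GeneConstraint,
    PredictorScores,
    ResourceBundle,
    TranscriptModel,
    classify_consequence,
    dist_to_transcript_end,
    is_major_transcript,
    join_annotations,
)
from triodnv.denovo_scan import DenovoCandidate
from triodnv.errors import DataError
from triodnv.trio_io import TrioGenotypeRecord

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


def _translate(codon):
    """Independent codon translation via the published standard table."""
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def _toy_transcript(strand="+", seed=7):
    """Two-exon transcript with short UTRs; CDS ends in a forced TAA stop."""
    rng = np.random.default_rng(seed)
    genome = list(rng.choice(list("ACGT"), size=400))
    exons = ((100, 130), (160, 202))  # cDNA length 72
    tm = TranscriptModel(
        "NM_TOY", "TOY", "1", strand, exons,
        cds_start=exons[0][0], cds_end=exons[-1][1],
    )
    # CDS occupies cDNA [6, 66): 60 bases = 20 codons incl. stop
    g_first = tm.cdna_to_genomic(6)
    g_last = tm.cdna_to_genomic(65)
    tm = TranscriptModel(
        "NM_TOY", "TOY", "1", strand, exons,
        cds_start=min(g_first, g_last), cds_end=max(g_first, g_last) + 1,
        exon_expression={"fetal_cortex": (5.0, 0.2)},
    )
    for k, base in enumerate("TAA"):
        g = tm.cdna_to_genomic(63 + k)
        genome[g] = base if strand == "+" else base.translate(_COMP)
    # avoid premature stops so stop_loss only occurs at the real stop codon
    cdna = "".join("".join(genome[s:e]) for s, e in exons)
    cdna = cdna if strand == "+" else _revcomp(cdna)
    for ci in range(19):
        codon = cdna[6 + 3 * ci : 9 + 3 * ci]
        if _translate(codon) == "*":
            g = tm.cdna_to_genomic(6 + 3 * ci)
            genome[g] = "C" if strand == "+" else "G"
    return tm, {"1": "".join(genome)}


def _oracle_snv_class(tm, genome, pos0, alt):
    """Brute-force oracle: manual splicing + published codon table."""
    cdna_seq = "".join(genome[tm.chrom][s:e] for s, e in tm.exons)
    idx_plus = None
    cum = 0
    for s, e in tm.exons:
        if s <= pos0 < e:
            idx_plus = cum + pos0 - s
        cum += e - s
    if idx_plus is None:
        dists = []
        for (s1, e1), (s2, _) in zip(tm.exons, tm.exons[1:]):
            if e1 <= pos0 < s2:
                dists = [pos0 - e1 + 1, s2 - pos0]
        return "splice" if dists and min(dists) <= 2 else "other"
    alt_plus = alt
    if tm.strand == "-":
        cdna_seq = _revcomp(cdna_seq)
        idx = len(cdna_seq) - 1 - idx_plus
        alt_c = alt_plus.translate(_COMP)
    else:
        idx = idx_plus
        alt_c = alt_plus
    lo, hi = 6, 66
    if not (lo <= idx < hi):
        return "other"
    off = idx - lo
    ci, within = divmod(off, 3)
    codon = cdna_seq[lo + 3 * ci : lo + 3 * ci + 3]
    alt_codon = codon[:within] + alt_c + codon[within + 1 :]
    aa0, aa1 = _translate(codon), _translate(alt_codon)
    if aa0 == aa1:
        return "synonymous"
    if aa1 == "*":
        return "stop_gain"
    if aa0 == "*":
        return "stop_loss"
    return "missense"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_all_cds_snvs_match_translation_oracle(strand):
    """Every possible SNV across the whole transcript matches a brute-force
    splicing + codon-translation oracle."""
    tm, genome = _toy_transcript(strand)
    n_checked = 0
    for pos0 in range(tm.tx_start, tm.tx_end):
        ref = genome["1"][pos0]
        for alt in "ACGT":
            if alt == ref:
                continue
            got = classify_consequence(pos0 + 1, ref, alt, tm, genome)
            assert got.value == _oracle_snv_class(tm, genome, pos0, alt), (
                strand, pos0, ref, alt
            )
            n_checked += 1
    assert n_checked == 3 * (tm.tx_end - tm.tx_start)


@pytest.mark.parametrize("offset,expected", [
    (1, Consequence.SPLICE), (2, Consequence.SPLICE),
    (3, Consequence.OTHER), (5, Consequence.OTHER),
])
def test_splice_only_at_main_donor_acceptor_sites(offset, expected):
    tm, genome = _toy_transcript("+")
    donor = tm.exons[0][1]
    pos0 = donor + offset - 1
    ref = genome["1"][pos0]
    alt = "A" if ref != "A" else "G"
    assert classify_consequence(pos0 + 1, ref, alt, tm, genome) is expected


def test_indel_frame_rules():
    tm, genome = _toy_transcript("+")
    g = tm.cdna_to_genomic(30)  # mid-CDS
    seq = genome["1"]
    anchor, deleted = seq[g - 1], seq[g]
    # 1-bp deletion -> frameshift
    assert classify_consequence(g, anchor + deleted, anchor, tm, genome) is (
        Consequence.FRAMESHIFT
    )
    # 3-bp deletion -> in-frame, not frameshift
    assert classify_consequence(g, seq[g - 1 : g + 3], anchor, tm, genome) is (
        Consequence.OTHER
    )


def test_variant_outside_transcript_is_error():
    tm, genome = _toy_transcript("+")
    with pytest.raises(DataError, match="outside transcript"):
        classify_consequence(1, "A", "G", tm, genome)


def test_reference_mismatch_is_error():
    tm, genome = _toy_transcript("+")
    g = tm.cdna_to_genomic(30)
    wrong = "A" if genome["1"][g] != "A" else "C"
    with pytest.raises(DataError, match="mismatch"):
        classify_consequence(g + 1, wrong, "T" if wrong != "T" else "G", tm, genome)


# --------------------------------------------------------------------------
# distance to translation stop

def test_distance_counts_cdna_bases_to_stop():
    tm, _ = _toy_transcript("+")
    # stop codon occupies cDNA [63, 66)
    pos_30_before = tm.cdna_to_genomic(33) + 1
    assert dist_to_transcript_end(pos_30_before, tm) == (30, None)
    at_stop = tm.cdna_to_genomic(63) + 1
    assert dist_to_transcript_end(at_stop, tm) == (0, None)
    past = tm.cdna_to_genomic(67) + 1  # 3' UTR
    dist, flag = dist_to_transcript_end(past, tm)
    assert dist == 0 and flag is not None


def test_distance_is_strand_symmetric():
    """A minus-strand transcript mirrors its plus-strand counterpart."""
    plus, _ = _toy_transcript("+")
    minus, _ = _toy_transcript("-")
    for cdna in (10, 33, 50, 63):
        d_plus = dist_to_transcript_end(plus.cdna_to_genomic(cdna) + 1, plus)
        d_minus = dist_to_transcript_end(minus.cdna_to_genomic(cdna) + 1, minus)
        assert d_plus == d_minus


@pytest.mark.parametrize("strand", ["+", "-"])
def test_consequence_is_strand_symmetric(strand):
    """Planting the same codon change on either strand gives the same call."""
    tm, genome = _toy_transcript(strand)
    # force codon 5 (cDNA 21..23) to TGG, mutate to TGA -> stop_gain
    g_codon = [tm.cdna_to_genomic(21 + k) for k in range(3)]
    seq = list(genome["1"])
    for g, b in zip(g_codon, "TGG"):
        seq[g] = b if strand == "+" else b.translate(_COMP)
    genome = {"1": "".join(seq)}
    g = tm.cdna_to_genomic(23)
    ref = "G" if strand == "+" else "C"
    alt = "A" if strand == "+" else "T"
    assert classify_consequence(g + 1, ref, alt, tm, genome) is Consequence.STOP_GAIN


# --------------------------------------------------------------------------
# major-transcript rule and the join

def test_major_transcript_expression_floor():
    tm, _ = _toy_transcript("+")  # exon FPKM (5.0, 0.2) in fetal cortex
    assert is_major_transcript(tm, 0, expression_floor=1.0) == (True, None)
    assert is_major_transcript(tm, 1, expression_floor=1.0)[0] is False
    assert is_major_transcript(tm, 1, expression_floor=0.0) == (True, None)
    bare = TranscriptModel(
        "NM_X", "X", "1", "+", ((0, 30),), cds_start=0, cds_end=30
    )
    value, flag = is_major_transcript(bare, 0)
    assert value is False and flag is not None


def _candidate(tm, genome, cdna, alt=None):
    g = tm.cdna_to_genomic(cdna)
    ref = genome["1"][g]
    alt = alt or ("A" if ref != "A" else "G")
    rec = TrioGenotypeRecord(
        "1", g + 1, ref, alt, (0, 1), (0, 0), (0, 0),
        child_dp=30, mother_dp=30, father_dp=30, child_alt_reads=15,
    )
    return DenovoCandidate(rec, "T1")


def test_join_is_total_and_flags_missing_resources():
    tm, genome = _toy_transcript("+")
    resources = ResourceBundle(
        constraint={},  # TOY gene absent -> UNSCORED
        transcripts=(tm,),
        genome=genome,
        ndd_genes=frozenset({"TOY"}),
    )
    candidates = [_candidate(tm, genome, 20), _candidate(tm, genome, 40)]
    # one candidate on a contig with no transcript at all
    stray = TrioGenotypeRecord("2", 50, "A", "G", (0, 1), (0, 0), (0, 0),
                               child_dp=30, mother_dp=30, father_dp=30,
                               child_alt_reads=12)
    candidates.append(DenovoCandidate(stray, "T1"))
    anns = join_annotations(candidates, resources)
    assert len(anns) == len(candidates)  # total: flagged, never dropped
    assert all(FLAG_UNSCORED in a.flags for a in anns[:2])
    assert anns[2].gene is None and anns[2].flags


def test_join_populates_constraint_and_maf():
    tm, genome = _toy_transcript("+")
    cand = _candidate(tm, genome, 20)
    key = cand.record.key
    resources = ResourceBundle(
        constraint={"TOY": GeneConstraint("TOY", pli=1.0, loeuf=0.09, mis_z=3.2)},
        transcripts=(tm,),
        genome=genome,
        maf={key: 3.2e-5},
        predictor_scores={key: PredictorScores(mcap=0.03)},
        ndd_genes=frozenset({"TOY"}),
    )
    (ann,) = join_annotations([cand], resources)
    assert ann.constraint.pli == 1.0 and ann.constraint.loeuf == 0.09
    assert ann.maf == pytest.approx(3.2e-5)
    assert ann.scores.mcap == pytest.approx(0.03)
    assert ann.ndd_gene
    # absent from the frequency table means absent from the population
    (ann2,) = join_annotations([_candidate(tm, genome, 40)], resources)
    assert ann2.maf == 0.0
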