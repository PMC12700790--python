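"""Candidate de novo variant detection from trio genotype records.

A de novo candidate is a site where the child carries the alternate allele
while both parents are confidently homozygous reference: all three samples
covered at >= ``min_depth`` (20x by default) and each parent showing at
most ``max_parent_alt_reads`` stray alternate reads.  Sites with a missing
genotype in any member are never candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .trio_io import TrioGenotypeRecord

#: every emitted candidate still requires orthogonal confirmation
#: (IGV inspection / Sanger) before being reported
FLAG_NEEDS_CONFIRMATION = "NEEDS_CONFIRMATION"
#: child called homozygous (or hemizygous) for the alternate allele —
#: biologically implausible for a germline de novo, kept for audit
FLAG_HOMOZYGOUS_ALT = "HOMALT_SUSPECT"


@dataclass(frozen=True)
class DenovoCandidate:
    record: TrioGenotypeRecord
    trio_id: str
    qc_flags: frozenset[str] = frozenset()

    @property
    def key(self):
        return self.record.key


def _is_denovo(
    r: TrioGenotypeRecord, min_depth: int, max_parent_alt_reads: int
) -> bool:
    if r.child_gt is None or r.mother_gt is None or r.father_gt is None:
        return False
    if 1 not in r.child_gt:
        return False
    if any(a != 0 for a in r.mother_gt) or any(a != 0 for a in r.father_gt):
        return False
    if min(r.child_dp, r.mother_dp, r.father_dp) < min_depth:
        return False
    if max(r.mother_alt_reads, r.father_alt_reads) > max_parent_alt_reads:
        return False
    return True


def detect_denovo(
    records: Sequence[TrioGenotypeRecord],
    trio_id: str = "",
    min_depth: int = 20,
    max_parent_alt_reads: int = 1,
) -> list[DenovoCandidate]:
    """Return the de novo candidates among ``records``, order-preserving.

    Hemizygous sites (single-allele genotypes on X/Y in males) follow the
    same rule applied to the one-allele genotype.
    """
    if min_depth < 1:
        raise ConfigurationError(f"min_depth must be >= 1, got {min_depth}")
    out = []
    for r in records:
        if not _is_denovo(r, min_depth, max_parent_alt_reads):
            continue
        flags = {FLAG_NEEDS_CONFIRMATION}
        assert r.child_gt is not None
        if all(a == 1 for a in r.child_gt) and len(r.child_gt) > 1:
            flags.add(FLAG_HOMOZYGOUS_ALT)
        out.append(DenovoCandidate(r, trio_id, frozenset(flags)))
    return out


def write_candidates_tsv(
    candidates: Iterable[DenovoCandidate], path: str | Path
) -> None:
    header = [
        "trio_id", "chrom", "pos", "ref", "alt",
        "child_dp", "mother_dp", "father_dp",
        "mother_alt_reads", "father_alt_reads", "qc_flags",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in candidates:
            r = c.record
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.trio_id, r.chrom, r.pos, r.ref, r.alt,
                        r.child_dp, r.mother_dp, r.father_dp,
                        r.mother_alt_reads, r.father_alt_reads,
                        ",".join(sorted(c.qc_flags)),
                    ]
                )
                + "\n"
            )
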