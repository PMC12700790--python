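"""Trio VCF input/output, pedigree handling and variant normalization.

Coordinates are 1-based inclusive externally (the VCF convention) and
0-based half-open everywhere inside the package.  Only chromosomes 1-22,
X and Y (with or without a ``chr`` prefix) are processed; records on other
contigs are skipped and counted in the module logger.

Each trio is read from three single-sample VCF files (child, mother,
father).  Parental files are expected to report genotypes (including
homozygous-reference calls with depths) at the sites of interest, the way
per-sample gVCF-style exports do; a site absent from a parental file is a
missing parental genotype.  Missing genotypes are retained at read time —
the de novo scanner excludes them later, so the audit trace can report
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

_ALLOWED_CHROMS = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y"]
)

#: genotype as a tuple of allele indices (0 = ref, 1 = alt); None = missing call
Genotype = tuple[int, ...] | None


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class Pedigree:
    """One parent-offspring trio and its recruitment cohort."""

    trio_id: str
    child_id: str
    mother_id: str
    father_id: str
    cohort: str = "SYNTHETIC"  # RESTART | MEGS | KST | SYNTHETIC

    def __post_init__(self):
        ids = {self.child_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ConfigurationError(
                f"trio {self.trio_id}: child/mother/father sample ids must be distinct"
            )


@dataclass(frozen=True)
class TrioGenotypeRecord:
    """One biallelic variant site with genotypes and depths for all trio members."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    child_gt: Genotype
    mother_gt: Genotype
    father_gt: Genotype
    child_dp: int = 0
    mother_dp: int = 0
    father_dp: int = 0
    child_alt_reads: int = 0
    mother_alt_reads: int = 0
    father_alt_reads: int = 0

    def __post_init__(self):
        if self.pos < 1:
            raise DataError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise DataError(
                    f"alleles must be non-empty uppercase ACGT strings, got "
                    f"{self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}"
                )
        for who in ("child", "mother", "father"):
            dp = getattr(self, f"{who}_dp")
            ar = getattr(self, f"{who}_alt_reads")
            if dp < 0 or ar < 0 or ar > dp:
                raise DataError(
                    f"{who} depth/alt-read counts inconsistent at "
                    f"{self.chrom}:{self.pos} (dp={dp}, alt_reads={ar})"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_pedigree(path: str | Path) -> list[Pedigree]:
    """Read a 4/5-column TSV: trio_id, child, mother, father[, cohort]."""
    pedigrees = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("trio_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DataError(f"{path}: pedigree line {i} has <4 columns")
            cohort = fields[4] if len(fields) > 4 else "SYNTHETIC"
            pedigrees.append(Pedigree(fields[0], fields[1], fields[2], fields[3], cohort))
    seen: set[str] = set()
    for ped in pedigrees:
        if ped.trio_id in seen:
            raise ConfigurationError(f"duplicate trio_id {ped.trio_id}")
        seen.add(ped.trio_id)
    return pedigrees


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_context: str,
    context_start: int = 1,
) -> tuple[int, str, str]:
    """Left-align and trim a variant against a reference context string.

    ``reference_context`` is the reference sequence starting at 1-based
    genomic position ``context_start``.  Returns the minimal, left-most
    equivalent ``(pos, ref, alt)``.  Idempotent.
    """
    p = pos - context_start
    if p < 0 or p + len(ref) > len(reference_context):
        raise DataError(f"context does not cover {chrom}:{pos}:{ref}")
    if reference_context[p : p + len(ref)] != ref:
        raise DataError(
            f"ref allele {ref!r} does not match reference context at {chrom}:{pos}"
        )
    ref_a, alt_a = ref, alt
    while True:
        if ref_a and alt_a and ref_a[-1] == alt_a[-1] and (len(ref_a) > 1 or len(alt_a) > 1):
            ref_a, alt_a = ref_a[:-1], alt_a[:-1]
            continue
        if not ref_a or not alt_a:
            if p > 0:
                p -= 1
                base = reference_context[p]
                ref_a, alt_a = base + ref_a, base + alt_a
                continue
            # repeat run reaches the start of the context: anchor the
            # representation at position 1 with the following base instead
            if p + len(ref_a) >= len(reference_context):
                raise DataError(
                    f"context too short to represent the variant at {chrom}:{pos}"
                )
            base = reference_context[p + len(ref_a)]
            ref_a, alt_a = ref_a + base, alt_a + base
        break
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[0] == alt_a[0]:
        ref_a, alt_a = ref_a[1:], alt_a[1:]
        p += 1
    return (p + context_start, ref_a, alt_a)


# --------------------------------------------------------------------------
# VCF reading

@dataclass
class _SampleCall:
    gt: Genotype
    dp: int
    alt_reads: int


def _decompose_site(
    rec, sample: str, reference: Mapping[str, str] | None
) -> list[tuple[tuple[str, int, str, str], _SampleCall]]:
    """Split one (possibly multiallelic) VCF record into biallelic calls.

    For each alternate allele, allele indices equal to that allele map to 1
    and every other called allele (reference or another alternate) maps
    to 0, which conserves the total non-reference allele count across the
    decomposed records.
    """
    chrom = _norm_chrom(rec.chrom)
    call = rec.samples[sample]
    raw_gt = call.get("GT")
    dp = call.get("DP")
    ad = call.get("AD")
    if dp is None:
        dp = sum(a for a in ad if a is not None) if ad else 0
    out = []
    alts = rec.alts or ()
    for ai, alt in enumerate(alts, start=1):
        if alt is None or alt in ("*", "<NON_REF>"):
            continue
        ref, altseq = rec.ref.upper(), alt.upper()
        pos = rec.pos
        # trim shared suffix/prefix; full left-alignment needs the reference
        if reference is not None and chrom in reference:
            pos, ref, altseq = normalize_variant(
                chrom, pos, ref, altseq, reference[chrom], context_start=1
            )
        else:
            while len(ref) > 1 and len(altseq) > 1 and ref[-1] == altseq[-1]:
                ref, altseq = ref[:-1], altseq[:-1]
            while len(ref) > 1 and len(altseq) > 1 and ref[0] == altseq[0]:
                ref, altseq = ref[1:], altseq[1:]
                pos += 1
        if ref == altseq:
            continue
        if raw_gt is None or any(a is None for a in raw_gt):
            gt: Genotype = None
        else:
            gt = tuple(1 if a == ai else 0 for a in raw_gt)
        alt_reads = 0
        if ad is not None and len(ad) > ai and ad[ai] is not None:
            alt_reads = int(ad[ai])
        alt_reads = min(alt_reads, int(dp or 0))
        out.append(((chrom, pos, ref, altseq), _SampleCall(gt, int(dp or 0), alt_reads)))
    return out


def _read_sample_vcf(
    path: str | Path, sample_id: str, reference: Mapping[str, str] | None
) -> dict[tuple[str, int, str, str], _SampleCall]:
    calls: dict[tuple[str, int, str, str], _SampleCall] = {}
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        if sample_id not in list(vcf.header.samples):
            raise ConfigurationError(
                f"{path}: sample {sample_id!r} not found in VCF header "
                f"(has {list(vcf.header.samples)})"
            )
        for rec in vcf:
            if _norm_chrom(rec.chrom) not in _ALLOWED_CHROMS:
                skipped += 1
                continue
            for key, call in _decompose_site(rec, sample_id, reference):
                calls[key] = call
    if skipped:
        log.info("%s: skipped %d records on non-standard contigs", path, skipped)
    return calls


_CHROM_ORDER = {c: i for i, c in enumerate([str(i) for i in range(1, 23)] + ["X", "Y"])}


def read_trio(
    vcf_paths: Sequence[str | Path],
    pedigree: Pedigree,
    reference: Mapping[str, str] | None = None,
) -> list[TrioGenotypeRecord]:
    """Read (child, mother, father) VCFs into trio genotype records.

    Returns one record per biallelic site at which the child carries at
    least one non-reference allele.  Multiallelic sites are decomposed;
    indels are trimmed and, when ``reference`` (chrom -> sequence string)
    is supplied, left-aligned.
    """
    if len(vcf_paths) != 3:
        raise ConfigurationError("read_trio expects exactly three VCF paths")
    child = _read_sample_vcf(vcf_paths[0], pedigree.child_id, reference)
    mother = _read_sample_vcf(vcf_paths[1], pedigree.mother_id, reference)
    father = _read_sample_vcf(vcf_paths[2], pedigree.father_id, reference)

    records = []
    for key in sorted(child, key=lambda k: (_CHROM_ORDER[k[0]], k[1], k[2], k[3])):
        c = child[key]
        if c.gt is None or not any(a == 1 for a in c.gt):
            continue
        m = mother.get(key, _SampleCall(None, 0, 0))
        f = father.get(key, _SampleCall(None, 0, 0))
        chrom, pos, ref, alt = key
        records.append(
            TrioGenotypeRecord(
                chrom, pos, ref, alt,
                child_gt=c.gt, mother_gt=m.gt, father_gt=f.gt,
                child_dp=c.dp, mother_dp=m.dp, father_dp=f.dp,
                child_alt_reads=c.alt_reads,
                mother_alt_reads=m.alt_reads,
                father_alt_reads=f.alt_reads,
            )
        )
    return records


# --------------------------------------------------------------------------
# VCF writing (round-trip support)

def _make_header(sample: str, chroms: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for c in chroms:
        header.add_line(f"##contig=<ID={c},length=536870912>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_sample(sample)
    return header


def write_trio(
    records: Sequence[TrioGenotypeRecord],
    pedigree: Pedigree,
    out_dir: str | Path,
) -> tuple[Path, Path, Path]:
    """Write records back out as three single-sample VCF 4.2 files.

    Parental homozygous-reference calls at the child's variant sites are
    written explicitly so that ``read_trio`` round-trips the records.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms = sorted({r.chrom for r in records}, key=lambda c: _CHROM_ORDER[c])
    paths = []
    members = [
        ("child", pedigree.child_id),
        ("mother", pedigree.mother_id),
        ("father", pedigree.father_id),
    ]
    for who, sample in members:
        path = out_dir / f"{pedigree.trio_id}_{who}.vcf"
        header = _make_header(sample, chroms)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for r in sorted(records, key=lambda r: (_CHROM_ORDER[r.chrom], r.pos)):
                rec = vcf.new_record(
                    contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
                )
                gt = getattr(r, f"{who}_gt")
                dp = getattr(r, f"{who}_dp")
                ar = getattr(r, f"{who}_alt_reads")
                rec.samples[sample]["GT"] = gt if gt is not None else (None, None)
                rec.samples[sample]["DP"] = dp
                rec.samples[sample]["AD"] = (dp - ar, ar)
                vcf.write(rec)
        paths.append(path)
    return tuple(paths)  # type: ignore[return-value]
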