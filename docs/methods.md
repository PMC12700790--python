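# Methods

This note documents the models and procedures `triodnv` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## De novo detection model

A de novo candidate at a biallelic site requires, simultaneously:

* the child's called genotype contains the alternate allele;
* both parental called genotypes are homozygous reference;
* all three samples are covered at ≥ `min_depth` (default **20×**, the
  coverage floor of the source analysis);
* each parent shows ≤ `max_parent_alt_reads` alternate-supporting reads
  (default **1**; tolerating a single stray read guards against
  sequencing error without admitting low-fraction parental mosaicism —
  the source analysis relied on visual inspection here, so the bound is
  configurable).

Sites with a missing genotype in any member are retained by the reader
and excluded by the scanner, so the audit trail can report them. Children
called homozygous-alt are biologically implausible as germline de novos
and are flagged (`HOMALT_SUSPECT`) but not excluded. Every candidate
carries a `NEEDS_CONFIRMATION` flag: the pipeline does not substitute for
orthogonal validation (IGV / Sanger). Hemizygous male X/Y sites use the
same rule on the single-allele genotype; no sex-aware depth adjustment is
made.

Coordinates are 1-based inclusive at the VCF surface and 0-based
half-open internally. Multiallelic sites are decomposed one alternate
allele at a time; in each decomposed record, alleles equal to that
alternate map to 1 and all other called alleles map to 0, which conserves
the summed non-reference allele count. Indels are trimmed and, when a
reference sequence is available, left-aligned; a repeat run that reaches
the start of the supplied context is anchored at position 1 by
right-extension. Only chromosomes 1–22, X and Y are processed; other
contigs are counted and skipped.

## Annotation features

* **Consequence** is computed on the single designated transcript per
  gene by codon translation for CDS SNVs (synonymous / missense /
  stop-gain / stop-loss), by length change modulo 3 for coding indels
  (frameshift vs in-frame, the latter classed `other`), and by position
  for intronic SNVs: only the ±1/±2 dinucleotides of an exon boundary are
  `splice` (the main donor/acceptor sites); deeper positions are
  `other`. No transcript-picking heuristic exists — resources designate
  one isoform per gene, as the source tables did.
* **Distance to transcript end** is measured in cDNA bases to the start
  of the stop codon, not to the polyadenylation site: the 50-bp end rule
  exists to drop loss-of-function variants likely to escape
  nonsense-mediated decay, which is a CDS-position property. A variant in
  the stop codon has distance 0; downstream positions return 0 with a
  `PAST_STOP` flag.
* **Major transcript**: an exon counts as expressed when its FPKM-like
  value is ≥ `expression_floor` (default **1.0**) in at least one brain
  tissue context; no published number exists for this floor, so it is a
  package default and configurable.
* The join is total: candidates with a missing constraint row are flagged
  `UNSCORED`, candidates outside every transcript `NO_TRANSCRIPT`; none
  are dropped. A variant absent from the frequency table has MAF 0
  (absent from the population reference).

## Filter cascade

Gates run in a fixed order — non-synonymous → secondary-findings removal
→ constraint → pLoF position — each a pure predicate, so order cannot
change the survivor set; it only determines which gate a trace records as
decisive. Thresholds (all strict inequalities, matching the stated
filtering rules): pLI > 0.9 **or** LOEUF < 0.6 for pLoF; mis_z > 2.5 for
missense. The ACMG secondary-findings list (v3.1, 78 genes) is matched
case-insensitively. Predictor dichotomization: M-CAP > 0.025,
REVEL > 0.5, PrimateAI > 0.8, AlphaMissense > 0.564 are damaging;
AlphaMissense additionally has an ambiguous band (0.34, 0.564] — 0.34 is
the tool's published likely-benign bound, which the source analysis left
implicit. Predictor calls never reject a variant at this stage (the
published missense table retains variants with tolerated/ambiguous
calls); they feed PP3/BP4 downstream.

## ACMG engine

Six evidence codes are implemented — exactly those a confirmed de novo
plus population absence plus in-silico evidence can support: PVS1 (pLoF
where LoF is an established disease mechanism), PS2 (confirmed de novo),
PM2 (absent from population databases), PP2 (missense in a
missense-depleted gene), PP3 and BP4. Other codes are rejected with a
clear error rather than silently ignored.

Three assignment rules are not stated anywhere in the source material and
were inferred from the complete pattern of the published missense table
(they reproduce every row, and are configurable):

* **PP3** requires ≥ 2 of the 4 predictor calls to be damaging;
* **BP4** is triggered by ≥ 1 tolerated call (ambiguous calls count for
  neither);
* **PM2** requires MAF exactly 0 — a variant seen once (8 × 10⁻⁶) lacks
  PM2 in the published table, so "rare" is not enough.

Combination follows the standard five-tier combining rules restricted to
the implemented codes (e.g. Pathogenic = PVS1 + 1 Strong, or PVS1 + 1
Moderate + 1 Supporting; Likely pathogenic = 1 Strong + 1–2 Moderate, 1
Strong + ≥ 2 Supporting, or PVS1 + 1 Moderate). Any benign-supporting
evidence yields VUS: a single BP code cannot reach Likely benign, and BP4
alongside pathogenic evidence is conflicting evidence. The combiner is
deterministic and order-invariant; an exhaustive 64-subset truth table is
frozen in the test suite.

Variants in genes not established for a monogenic neurodevelopmental
disorder receive no evidence codes. Constrained-gene pLoF survivors are
labelled "variant of interest in GUS". For missense survivors the screen
requires **unanimous** damaging calls (4 of 4, configurable): the
published table leaves missense variants with 2 of 4 damaging calls in
GUS genes unlabelled, so the two-call PP3 bar is demonstrably not the bar
used for the variant-of-interest label, and only pLoF variants were in
fact labelled.

## Phenotype rules

Persistent: SSI ≥ 11, or SSI ∈ {9, 10} with parent or clinician reporting
stuttering. Transient: SSI ≤ 8 with both reports explicitly negative.
Everything else — conflicts or missing reports — is ambiguous
(conservative; the source rules do not cover missing reports). MEGS and
KST probands are persistent by recruitment design and bypass the SSI
rule. Trio eligibility: excluded when a parent ever stuttered, > 1
second-degree, > 2 third-degree, or > 2 combined second- plus
third-degree relatives stutter; the combined rule is interpreted as
counting distinct individuals.

## Gene-set statistics

* Fisher exact module enrichment is two-sided by the probability-mass
  method (sum of same-margin tables with probability ≤ observed), the
  conventional exact-test definition; degenerate margins return p = 1
  with a flag.
* Pseudobulk spatial expression averages normalized counts per cluster,
  then log-transforms; the transform is log₂(x + 1) — the source states
  only "log-transformed", so base and offset are package defaults and
  configurable. The operation is invariant to spot order and to batch
  splitting with weighted recombination.
* Bonferroni thresholds report both the exact α/m and its
  2-significant-digit form (0.05/24 → 0.0021); screening uses strict
  `p < threshold` on the exact value. MAGMA's gene-based and competitive
  gene-set regression are consumed as precomputed inputs, never
  recomputed — reproducing the enrichment betas would require external
  GWAS summary data.

## Synthetic-data generator

The generator builds a 72-kb artificial genome with eleven three-exon
transcript models (both strands), forces a TAA stop at each CDS end, and
plants one variant per scenario template by writing the required
reference codon into the genome and emitting the corresponding VCF
record. Sixteen templates cover: pathogenic stop-gain, likely-pathogenic
and VUS missense (all-damaging vs one-damaging predictor profiles, absent
vs seen-once MAF), GUS variants of interest, and one decoy per gate —
just-below-threshold constraint (pLI 0.89 / LOEUF 0.61), synonymous,
secondary-findings gene, near-stop pLoF with and without a rescuing
domain, canonical (+1) and non-canonical (+5) splice positions, low child
depth (15×) and two stray parental reads. Background sites are Mendelian
by construction (every child alternate allele is present in a parent).
Depths are Poisson (mean 60×, floored at 20× for planted variants unless
a template overrides); heterozygous alternate reads are Binomial(dp, ½).
All randomness flows from `SimulationConfig.seed`; a fixed seed
reproduces every file byte for byte.

What it does **not** emulate: read-level error, mapping artefacts,
population-realistic allele-frequency spectra, mosaicism, sex
chromosomes, multi-gene overlaps, or UTR/regulatory variation. Passing
the end-to-end truth-recovery test therefore demonstrates the logic of
the gates and the classifier, not calling performance on real exomes.

## Problem sizes and numerics

The default synthetic cohort is 4 trios × 150 sites with 16 planted
scenarios; the scanner-recovery property is checked across 20 seeds at 60
sites per trio, and the Fisher-vs-enumeration property exhaustively for
all 2×2 tables with total ≤ 28 plus 1500 seeded random tables with total
≤ 60 — sizes chosen so the full suite runs in well under a minute per
property while still covering every margin regime. Floating-point
comparisons in tests use relative tolerances of 10⁻⁹ for exact-test
probabilities. Ties at thresholds are resolved by the strict inequalities
stated above.

## Known limitations

* The published fixture rows carry predictor *calls*, not raw scores, so
  the table entry point exercises criteria assignment and combination but
  not score dichotomization (the synthetic path covers that).
* HGVS strings are pass-through from resources; the package does not
  generate or validate them.
* The cohort-scale numbers of the source study (383 de novo calls across
  84 trios, the 7313-gene background list, MAGMA enrichment betas) depend
  on access-restricted or external data and are not reproduced; the
  package reproduces the printed variant tables, the stratified yield,
  the gene-set construction and the Bonferroni screen, and validates the
  algorithms against independent oracles.
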