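# triodnv

Trio-exome **de novo variant prioritization and classification** for
developmental stuttering cohorts — from parent–offspring trio genotypes to
candidate de novo variants, through a gene-constraint filter cascade, to
ACMG five-tier classification, cohort yield summaries and gene-set
evaluation statistics.

## The problem

Developmental stuttering is a common childhood condition; in a minority of
children it persists into adulthood. Rare-variant screens in multiplex
families have implicated a handful of genes in monogenic stuttering, but a
complementary design — searching for **de novo variants** (present in a
child, absent from both unaffected parents) in independent parent–child
trios — had not been applied. This package implements that analysis as a
tested, reusable pipeline for trio whole-exome data:

1. **Trio I/O** — read child/mother/father VCFs against a pedigree,
   decompose multiallelic sites, left-align indels
   (`triodnv.trio_io`).
2. **De novo scan** — a site is a candidate when the child carries the
   alternate allele, both parents are homozygous reference, all three
   samples have ≥ 20× coverage, and each parent shows ≤ 1 stray alternate
   read (`triodnv.denovo_scan`).
3. **Annotation** — join candidates to gene constraint (pLI, LOEUF,
   mis_z), population frequency (gnomAD-style MAF), missense predictor
   scores, transcript models with per-exon brain expression, and protein
   domains; compute consequence class by codon translation
   (`triodnv.annotation`).
4. **Filter cascade** — keep non-synonymous variants outside the ACMG
   secondary-findings list; pLoF (stop-gain, frameshift, canonical splice,
   stop-loss) requires pLI > 0.9 **or** LOEUF < 0.6, missense requires
   mis_z > 2.5; pLoF additionally requires a brain-expressed major
   transcript and a position ≥ 50 bp from the translation stop unless in a
   functional domain (`triodnv.filters`). Every variant gets a complete
   audit trace.
5. **ACMG engine** — assign PVS1 / PS2 / PM2 / PP2 / PP3 / BP4 and combine
   them into Pathogenic / Likely pathogenic / VUS; variants in genes of
   unknown significance (GUS) are screened for "variant of interest"
   status instead (`triodnv.acmg`). Missense in-silico evidence uses
   M-CAP > 0.025, REVEL > 0.5, PrimateAI > 0.8, AlphaMissense > 0.564 as
   damaging cutoffs.
6. **Phenotype** — SSI-based persistent / transient / ambiguous
   categorization and family-history trio eligibility
   (`triodnv.phenotype`).
7. **Gene-set statistics** — two-sided Fisher exact module enrichment,
   pseudobulk spatial-cluster expression, Bonferroni screening of
   gene-based GWAS p-values (`triodnv.geneset`).
8. **Synthetic data** — a seeded generator producing trio VCFs with
   planted de novo variants and the full resource bundle, with a truth
   table recording each variant's intended gate outcome
   (`triodnv.synthetic`).

Because the cohort's raw sequencing data are access-restricted, the
package ships the published variant tables as checksummed TSV fixtures
(`triodnv/data/`) and exercises the full genomic path on synthetic
cohorts.

## Worked example

Classify the shipped pre-annotated variant tables and summarize the yield:

```bash
triodnv classify-tables
```

```
   proband stutter_status    gene consequence                criteria             classification
RESTART_11              P    FLT3   stop_gain                       - Variant of interest in GUS
   MEGS_14              P  SPTBN1   stop_gain          PVS1, PS2, PM2                 Pathogenic
 RESTART_8              A   IREB2  frameshift                       - Variant of interest in GUS
RESTART_15              P   PRPF8    missense      PS2, PM2, PP2, PP3          Likely pathogenic
RESTART_47              P    CHD4    missense      PS2, PP2, PP3, BP4                        VUS
...
RESTART_27              T  ZBTB7A    missense      PS2, PM2, PP2, PP3          Likely pathogenic
(L)P carriers by status: {'persistent': 2, 'transient': 2, 'ambiguous': 0}; stuttering-associated gene set: 12 genes
```

Reading: the *SPTBN1* stop-gain is a confirmed de novo (PS2) loss-of-
function variant (PVS1) absent from population databases (PM2) in a gene
with an established LoF disease mechanism, hence Pathogenic; *FLT3* and
*IREB2* are constrained-gene pLoF variants in genes of unknown
significance, flagged as variants of interest. Two of the four (likely)
pathogenic carriers stutter persistently and two transiently. The
stuttering-associated gene set (six prior family-study genes plus the six
genes highlighted here) has 12 members.

Run the full genomic pipeline on a synthetic cohort:

```bash
triodnv run --seed 1 --out-dir out/
triodnv geneset          # Bonferroni screen of the gene-based GWAS table
```

Or from Python:

```python
from triodnv import SimulationConfig, generate_cohort, run_pipeline

bundle = generate_cohort(SimulationConfig(seed=1))
result = run_pipeline(bundle.records_by_trio, bundle.resources, bundle.pedigrees)
print(result.summary.variant_counts)
# Counter({<TierClass.PATHOGENIC: 'Pathogenic'>: 3,
#          <TierClass.LIKELY_PATHOGENIC: 'Likely pathogenic'>: 2, ...})
```

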