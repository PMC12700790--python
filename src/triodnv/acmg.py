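"""ACMG evidence assignment and five-tier combination.

Six evidence codes are implemented — the codes that a confirmed de novo,
population-absence and in-silico evidence can support for this analysis:

* PVS1 (very strong): loss-of-function variant in a gene where LoF is an
  established disease mechanism,
* PS2 (strong): de novo with confirmed parentage,
* PM2 (moderate): absent from population reference databases,
* PP2 (supporting): missense in a gene depleted for missense variation,
* PP3 (supporting): computational evidence of a deleterious effect,
* BP4 (benign supporting): computational evidence of no effect.

PP3 requires at least two of the four missense predictors to call the
variant deleterious; BP4 is triggered by a single tolerated call; PM2
requires the variant to be entirely absent (MAF exactly 0 by default).
Variants in genes not established for a monogenic neurodevelopmental
disorder (NDD) receive no evidence codes: they are either flagged as a
"variant of interest in a gene of unknown significance (GUS)" when the
damaging-evidence screen fires, or left unclassified.

Combination follows the standard five-tier combining rules restricted to
the implemented codes; any benign-supporting evidence alongside (or
without sufficient) pathogenic evidence yields uncertain significance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .annotation import Consequence, VariantAnnotation
from .errors import ConfigurationError
from .filters import Call


class Code(enum.Enum):
    PVS1 = "PVS1"
    PS2 = "PS2"
    PM2 = "PM2"
    PP2 = "PP2"
    PP3 = "PP3"
    BP4 = "BP4"


class Strength(enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    BENIGN_SUPPORTING = "benign_supporting"


STRENGTH: dict[Code, Strength] = {
    Code.PVS1: Strength.VERY_STRONG,
    Code.PS2: Strength.STRONG,
    Code.PM2: Strength.MODERATE,
    Code.PP2: Strength.SUPPORTING,
    Code.PP3: Strength.SUPPORTING,
    Code.BP4: Strength.BENIGN_SUPPORTING,
}

#: canonical reporting order
CODE_ORDER = (Code.PVS1, Code.PS2, Code.PM2, Code.PP2, Code.PP3, Code.BP4)


class TierClass(enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "Likely benign"
    BENIGN = "Benign"
    VARIANT_OF_INTEREST_GUS = "Variant of interest in GUS"
    NOT_CLASSIFIED = "-"


@dataclass(frozen=True)
class CriteriaSet:
    codes: frozenset[Code]
    flags: frozenset[str] = frozenset()

    def __str__(self) -> str:
        return ", ".join(c.value for c in CODE_ORDER if c in self.codes)


@dataclass(frozen=True)
class GusAssessment:
    """Marker for variants in genes of unknown significance (no criteria)."""

    variant_of_interest: bool


@dataclass(frozen=True)
class AssignmentPolicy:
    pp3_min_damaging: int = 2       # D calls needed for PP3
    bp4_min_tolerated: int = 1      # T calls needed for BP4
    pm2_max_maf: float = 0.0        # MAF ceiling for "absent"
    pp2_misz_min: float = 2.5       # missense-constraint bound for PP2
    #: unanimous deleterious calls required to flag a GUS missense variant
    #: as a variant of interest (GUS pLoF variants always qualify, having
    #: already passed the constraint and position gates)
    gus_voi_min_damaging: int = 4


def assign_criteria(
    annotation: VariantAnnotation,
    predictor_calls: Mapping[str, Call] | None,
    policy: AssignmentPolicy | None = None,
) -> Union[CriteriaSet, GusAssessment]:
    """Assign evidence codes to a cascade survivor (or a GUS marker)."""
    policy = policy or AssignmentPolicy()
    calls = dict(predictor_calls or {})
    n_damaging = sum(1 for c in calls.values() if c is Call.D)
    n_tolerated = sum(1 for c in calls.values() if c is Call.T)

    if not annotation.ndd_gene:
        voi = annotation.is_plof or (
            annotation.consequence is Consequence.MISSENSE
            and n_damaging >= policy.gus_voi_min_damaging
        )
        return GusAssessment(variant_of_interest=voi)

    codes = {Code.PS2}  # confirmed de novo
    flags = set()
    if annotation.maf <= policy.pm2_max_maf:
        codes.add(Code.PM2)
    if annotation.is_plof and annotation.ndd_lof_mechanism:
        codes.add(Code.PVS1)
    if annotation.consequence is Consequence.MISSENSE:
        c = annotation.constraint
        if c is not None and c.mis_z is not None and c.mis_z > policy.pp2_misz_min:
            codes.add(Code.PP2)
        if any(c is Call.MISSING for c in calls.values()) or not calls:
            flags.add("MISSING_PREDICTOR_CALLS")
        if n_damaging >= policy.pp3_min_damaging:
            codes.add(Code.PP3)
        if n_tolerated >= policy.bp4_min_tolerated:
            codes.add(Code.BP4)
    return CriteriaSet(frozenset(codes), frozenset(flags))


def combine_criteria(criteria: CriteriaSet) -> TierClass:
    """Five-tier combination, restricted to the implemented codes.

    Deterministic and invariant to criteria ordering.  An empty set (or
    evidence insufficient for any rule) is uncertain significance.
    """
    for code in criteria.codes:
        if not isinstance(code, Code):
            raise ConfigurationError(f"unsupported evidence code {code!r}")
    n = {s: 0 for s in Strength}
    for code in criteria.codes:
        n[STRENGTH[code]] += 1
    nvs, ns = n[Strength.VERY_STRONG], n[Strength.STRONG]
    nm, np_ = n[Strength.MODERATE], n[Strength.SUPPORTING]
    nb = n[Strength.BENIGN_SUPPORTING]

    if nb >= 1:
        # a single benign-supporting code can neither reach (likely) benign
        # nor coexist with pathogenic evidence without conflict
        return TierClass.VUS
    pathogenic = nvs >= 1 and (ns >= 1 or (nm >= 1 and np_ >= 1) or np_ >= 2)
    if pathogenic:
        return TierClass.PATHOGENIC
    likely = (
        (nvs >= 1 and nm == 1)
        or (ns >= 1 and 1 <= nm <= 2)
        or (ns >= 1 and np_ >= 2)
        or nm >= 3
        or (nm == 2 and np_ >= 2)
        or (nm == 1 and np_ >= 4)
    )
    if likely:
        return TierClass.LIKELY_PATHOGENIC
    return TierClass.VUS


@dataclass(frozen=True)
class Classification:
    criteria: Optional[CriteriaSet]  # None for GUS variants
    tier: TierClass


def classify_variant(
    annotation: VariantAnnotation,
    predictor_calls: Mapping[str, Call] | None,
    policy: AssignmentPolicy | None = None,
) -> Classification:
    """Compose criteria assignment and combination.

    GUS variants bypass the combiner: they become "variant of interest in
    GUS" when the damaging-evidence screen fires and stay unclassified
    otherwise.
    """
    assigned = assign_criteria(annotation, predictor_calls, policy)
    if isinstance(assigned, GusAssessment):
        tier = (
            TierClass.VARIANT_OF_INTEREST_GUS
            if assigned.variant_of_interest
            else TierClass.NOT_CLASSIFIED
        )
        return Classification(None, tier)
    return Classification(assigned, combine_criteria(assigned))
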