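"""Cohort phenotype rules: stuttering-status assignment and trio eligibility.

RESTART probands are categorized from the Stuttering Severity Instrument
(SSI-4) score combined with parent and clinician reports; MEGS and KST
probands stutter persistently by recruitment design.  Trios are excluded
when a parent ever stuttered or when the reported family history exceeds
the allowed second/third-degree counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .errors import DataError


class StutterStatus(enum.Enum):
    PERSISTENT = "persistent"
    TRANSIENT = "transient"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PhenotypeRecord:
    proband_id: str
    cohort: str  # RESTART | MEGS | KST | SYNTHETIC
    ssi_score: Optional[int] = None
    parent_reports_stuttering: Optional[bool] = None
    clinician_reports_stuttering: Optional[bool] = None
    parent_ever_stuttered: bool = False
    n_second_degree: int = 0
    n_third_degree: int = 0

    def __post_init__(self):
        if self.n_second_degree < 0 or self.n_third_degree < 0:
            raise DataError("family-history counts must be >= 0")
        if self.ssi_score is not None and self.ssi_score < 0:
            raise DataError("SSI score must be >= 0")


def classify_status(record: PhenotypeRecord) -> StutterStatus:
    """Assign persistent / transient / ambiguous stuttering status.

    Persistent: SSI >= 11, or SSI in {9, 10} with parent or clinician
    reporting presence of stuttering.  Transient: SSI <= 8 with both
    parent and clinician explicitly reporting absence.  Everything else —
    including conflicting or missing reports — is ambiguous.  MEGS and
    KST probands are persistent by recruitment criteria.
    """
    if record.cohort in ("MEGS", "KST"):
        return StutterStatus.PERSISTENT
    ssi = record.ssi_score
    if ssi is None:
        raise DataError(
            f"{record.proband_id}: SSI score required for cohort {record.cohort}"
        )
    parent = record.parent_reports_stuttering
    clin = record.clinician_reports_stuttering
    if ssi >= 11:
        return StutterStatus.PERSISTENT
    if ssi in (9, 10):
        if parent is True or clin is True:
            return StutterStatus.PERSISTENT
        return StutterStatus.AMBIGUOUS
    # ssi <= 8
    if parent is False and clin is False:
        return StutterStatus.TRANSIENT
    return StutterStatus.AMBIGUOUS


def trio_eligible(record: PhenotypeRecord) -> tuple[bool, str]:
    """Family-history / parental-stuttering inclusion rule, with reason.

    Ineligible when a parent ever stuttered, when more than one
    second-degree or more than two third-degree relatives stutter, or when
    the combined second- plus third-degree count exceeds two.
    """
    if record.parent_ever_stuttered:
        return False, "a parent stuttered now or in the past"
    if record.n_second_degree > 1:
        return False, f"{record.n_second_degree} second-degree relatives stutter (>1)"
    if record.n_third_degree > 2:
        return False, f"{record.n_third_degree} third-degree relatives stutter (>2)"
    total = record.n_second_degree + record.n_third_degree
    if total > 2:
        return False, f"{total} second- plus third-degree relatives stutter (>2)"
    return True, "eligible"
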