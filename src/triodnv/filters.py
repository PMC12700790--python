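"""The ordered filter cascade applied to annotated de novo variants.

Gate order: non-synonymous -> ACMG secondary-findings removal -> gene
constraint -> pLoF position rules.  Each gate is a pure predicate, so the
order cannot change the survivor set; it only fixes which gate a rejected
variant's trace records as decisive.  Missense predictor calls (M-CAP,
REVEL, PrimateAI, AlphaMissense dichotomized at their published damaging
thresholds) are computed for survivors but never reject a variant here —
they feed the PP3/BP4 evidence codes downstream.

Threshold inequalities are strict (pLI > 0.9, LOEUF < 0.6, mis_z > 2.5,
score > cutoff); pLI and LOEUF are combined with OR.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .annotation import Consequence, PredictorScores, VariantAnnotation
from .errors import ConfigurationError

#: ACMG secondary-findings gene list, v3.1 (actionable incidental findings);
#: genes on this list are removed before filtering and interpretation.
ACMG_SF_V31 = frozenset(
    """ACTA2 ACTC1 ACVRL1 APC APOB ATP7B BAG3 BMPR1A BRCA1 BRCA2 BTD CACNA1S
    CASQ2 COL3A1 DES DSC2 DSG2 DSP ENG FBN1 FLNC GAA GLA HFE HNF1A KCNH2
    KCNQ1 LDLR LMNA MAX MEN1 MLH1 MSH2 MSH6 MUTYH MYBPC3 MYH7 MYH11 MYL2
    MYL3 NF2 OTC PALB2 PCSK9 PKP2 PMS2 PRKAG2 PTEN RB1 RBM20 RET RPE65 RYR1
    RYR2 SCN5A SDHAF2 SDHB SDHC SDHD SMAD3 SMAD4 STK11 TGFBR1 TGFBR2
    TMEM127 TMEM43 TNNC1 TNNI3 TNNT2 TP53 TPM1 TRDN TSC1 TSC2 TTN TTR VHL
    WT1""".split()
)


class Call(enum.Enum):
    """Dichotomized predictor call: deleterious / tolerated / ambiguous."""

    D = "D"
    T = "T"
    A = "A"
    MISSING = "missing"


class Outcome(enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class FilterConfig:
    pli_min: float = 0.9
    loeuf_max: float = 0.6
    misz_min: float = 2.5
    end_distance_bp: int = 50
    mcap_min: float = 0.025
    revel_min: float = 0.5
    primateai_min: float = 0.8
    alphamissense_pathogenic_min: float = 0.564
    alphamissense_benign_max: float = 0.34
    acmg_sf_genes: frozenset[str] = ACMG_SF_V31

    def __post_init__(self):
        for name in (
            "pli_min", "loeuf_max", "misz_min", "mcap_min", "revel_min",
            "primateai_min", "alphamissense_pathogenic_min", "alphamissense_benign_max",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if not self.alphamissense_benign_max < self.alphamissense_pathogenic_min:
            raise ConfigurationError(
                "alphamissense_benign_max must be below alphamissense_pathogenic_min"
            )
        # SF genes are matched case-insensitively
        object.__setattr__(
            self, "acmg_sf_genes", frozenset(g.upper() for g in self.acmg_sf_genes)
        )


@dataclass(frozen=True)
class GateResult:
    gate: str
    outcome: Outcome
    reason: str = ""


@dataclass(frozen=True)
class FilterTrace:
    """Per-variant audit of every gate; decisive = first failing gate."""

    annotation: VariantAnnotation
    results: tuple[GateResult, ...]

    @property
    def passed(self) -> bool:
        return all(r.outcome is not Outcome.FAIL for r in self.results)

    @property
    def decisive_gate(self) -> Optional[str]:
        for r in self.results:
            if r.outcome is Outcome.FAIL:
                return r.gate
        return None


# --------------------------------------------------------------------------
# gates

def gate_nonsynonymous(ann: VariantAnnotation) -> GateResult:
    kept = ann.consequence in (
        Consequence.MISSENSE, Consequence.STOP_GAIN, Consequence.STOP_LOSS,
        Consequence.FRAMESHIFT, Consequence.SPLICE,
    )
    return GateResult(
        "nonsynonymous",
        Outcome.PASS if kept else Outcome.FAIL,
        "" if kept else f"consequence {ann.consequence.value} is not non-synonymous",
    )


def gate_acmg_sf(ann: VariantAnnotation, config: FilterConfig) -> GateResult:
    if not config.acmg_sf_genes:
        import warnings

        warnings.warn("empty ACMG SF gene set: secondary-findings gate is a no-op")
    gene = (ann.gene or "").upper()
    if gene and gene in config.acmg_sf_genes:
        return GateResult(
            "acmg_sf", Outcome.FAIL, f"{ann.gene} is an ACMG secondary-findings gene"
        )
    return GateResult("acmg_sf", Outcome.PASS)


def gate_constraint(ann: VariantAnnotation, config: FilterConfig) -> GateResult:
    c = ann.constraint
    if ann.is_plof:
        if c is None or (c.pli is None and c.loeuf is None):
            return GateResult("constraint", Outcome.FAIL, "MISSING constraint metrics")
        ok = (c.pli is not None and c.pli > config.pli_min) or (
            c.loeuf is not None and c.loeuf < config.loeuf_max
        )
        return GateResult(
            "constraint",
            Outcome.PASS if ok else Outcome.FAIL,
            "" if ok else f"pLI {c.pli} <= {config.pli_min} and LOEUF {c.loeuf} >= {config.loeuf_max}",
        )
    if ann.consequence is Consequence.MISSENSE:
        if c is None or c.mis_z is None:
            return GateResult("constraint", Outcome.FAIL, "MISSING mis_z")
        ok = c.mis_z > config.misz_min
        return GateResult(
            "constraint",
            Outcome.PASS if ok else Outcome.FAIL,
            "" if ok else f"mis_z {c.mis_z} <= {config.misz_min}",
        )
    return GateResult("constraint", Outcome.NOT_APPLICABLE)


def gate_plof_position(ann: VariantAnnotation, config: FilterConfig) -> GateResult:
    if not ann.is_plof:
        return GateResult("plof_position", Outcome.NOT_APPLICABLE)
    if not ann.is_major_transcript:
        return GateResult(
            "plof_position", Outcome.FAIL, "not in a major (brain-expressed) transcript"
        )
    if (
        ann.dist_to_transcript_end_bp < config.end_distance_bp
        and not ann.in_functional_domain
    ):
        return GateResult(
            "plof_position",
            Outcome.FAIL,
            f"within {config.end_distance_bp} bp of the translation stop, "
            "outside any functional domain",
        )
    if ann.consequence is Consequence.SPLICE and not ann.splice_canonical:
        return GateResult(
            "plof_position", Outcome.FAIL, "splice variant beyond the +/-2 dinucleotides"
        )
    return GateResult("plof_position", Outcome.PASS)


GATE_ORDER = ("nonsynonymous", "acmg_sf", "constraint", "plof_position")


def call_predictor(
    scores: Optional[PredictorScores], tool: str, config: FilterConfig
) -> Call:
    """Dichotomize one tool's score: D above the damaging cutoff, else T.

    AlphaMissense additionally has an ambiguous band between its
    likely-benign bound and its damaging cutoff.
    """
    thresholds = {
        "mcap": config.mcap_min,
        "revel": config.revel_min,
        "primateai": config.primateai_min,
        "alphamissense": config.alphamissense_pathogenic_min,
    }
    if tool not in thresholds:
        raise ConfigurationError(f"unknown predictor tool {tool!r}")
    score = getattr(scores, tool, None) if scores is not None else None
    if score is None:
        return Call.MISSING
    if score > thresholds[tool]:
        return Call.D
    if tool == "alphamissense" and score > config.alphamissense_benign_max:
        return Call.A
    return Call.T


PREDICTOR_TOOLS = ("mcap", "revel", "primateai", "alphamissense")


def call_all_predictors(
    scores: Optional[PredictorScores], config: FilterConfig
) -> dict[str, Call]:
    return {tool: call_predictor(scores, tool, config) for tool in PREDICTOR_TOOLS}


@dataclass(frozen=True)
class Survivor:
    annotation: VariantAnnotation
    predictor_calls: dict[str, Call]


@dataclass(frozen=True)
class CascadeResult:
    survivors: tuple[Survivor, ...]
    traces: tuple[FilterTrace, ...]

    @property
    def rejected(self) -> tuple[FilterTrace, ...]:
        return tuple(t for t in self.traces if not t.passed)


def run_cascade(
    annotations: Sequence[VariantAnnotation], config: FilterConfig | None = None
) -> CascadeResult:
    """Apply all gates in order; the traces partition the input."""
    config = config or FilterConfig()
    survivors, traces = [], []
    for ann in annotations:
        results = (
            gate_nonsynonymous(ann),
            gate_acmg_sf(ann, config),
            gate_constraint(ann, config),
            gate_plof_position(ann, config),
        )
        trace = FilterTrace(ann, results)
        traces.append(trace)
        if trace.passed:
            calls = call_all_predictors(ann.scores, config)
            survivors.append(Survivor(ann, calls))
    return CascadeResult(tuple(survivors), tuple(traces))
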