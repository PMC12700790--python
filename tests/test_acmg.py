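"""Evidence-code assignment and five-tier combination.

The frozen truth table below was enumerated by hand from the published
combining rules restricted to the six implemented codes (counting
very-strong / strong / moderate / supporting / benign-supporting
evidence) before the engine was written.
"""

import itertools

import pytest

from triodnv.acmg import (
    AssignmentPolicy,
    Code,
    CriteriaSet,
    GusAssessment,
    TierClass,
    assign_criteria,
    classify_variant,
    combine_criteria,
)
from triodnv.annotation import Consequence, GeneConstraint, VariantAnnotation
from triodnv.filters import Call


def _ann(consequence=Consequence.MISSENSE, ndd=True, lof_mech=False, maf=0.0,
         mis_z=4.0, gene="GENE"):
    return VariantAnnotation(
        candidate=None, gene=gene, transcript_id="NM_T",
        consequence=consequence, maf=maf,
        constraint=GeneConstraint(gene, pli=0.99, loeuf=0.1, mis_z=mis_z),
        ndd_gene=ndd, ndd_lof_mechanism=lof_mech,
    )


def _calls(pattern):
    return dict(zip(("mcap", "revel", "primateai", "alphamissense"),
                    (Call(c) for c in pattern)))


@pytest.mark.parametrize(
    "ann,calls,expected",
    [
        # stop-gain in an NDD gene with LoF mechanism, absent from gnomAD
        (_ann(Consequence.STOP_GAIN, lof_mech=True), None,
         {Code.PVS1, Code.PS2, Code.PM2}),
        # missense, seen in gnomAD (no PM2), unanimous deleterious
        (_ann(maf=3.2e-5), _calls("DDDD"), {Code.PS2, Code.PP2, Code.PP3}),
        # missense, absent, one deleterious + tolerated calls
        (_ann(), _calls("DTTT"), {Code.PS2, Code.PM2, Code.PP2, Code.BP4}),
        # two deleterious + two tolerated, seen once
        (_ann(maf=8.0e-6), _calls("DTDT"), {Code.PS2, Code.PP2, Code.PP3, Code.BP4}),
        # ambiguous calls count neither for PP3 nor BP4
        (_ann(), _calls("DDAA"), {Code.PS2, Code.PM2, Code.PP2, Code.PP3}),
        # missense without constraint support loses PP2
        (_ann(mis_z=2.0), _calls("DDDD"), {Code.PS2, Code.PM2, Code.PP3}),
    ],
)
def test_criteria_assignment_rules(ann, calls, expected):
    got = assign_criteria(ann, calls)
    assert isinstance(got, CriteriaSet)
    assert got.codes == frozenset(expected)


def test_gus_variants_get_marker_not_criteria():
    # pLoF in a constrained non-NDD gene -> variant of interest
    got = assign_criteria(_ann(Consequence.STOP_GAIN, ndd=False), None)
    assert got == GusAssessment(variant_of_interest=True)
    # missense in a non-NDD gene without unanimous deleterious calls -> neither
    got = assign_criteria(_ann(ndd=False), _calls("DDTA"))
    assert got == GusAssessment(variant_of_interest=False)
    # unanimous deleterious missense in a non-NDD gene -> variant of interest
    got = assign_criteria(_ann(ndd=False), _calls("DDDD"))
    assert got == GusAssessment(variant_of_interest=True)


def test_missing_predictor_calls_flagged_not_fatal():
    got = assign_criteria(_ann(), _calls("DD") | {"primateai": Call.MISSING,
                                                  "alphamissense": Call.MISSING})
    assert Code.PP3 in got.codes
    assert "MISSING_PREDICTOR_CALLS" in got.flags


# --------------------------------------------------------------------------
# combination

# hand-enumerated truth table over all 2^6 subsets of the implemented codes
TRUTH_TABLE = [
    ((), "VUS"),
    (("PVS1",), "VUS"),
    (("PS2",), "VUS"),
    (("PM2",), "VUS"),
    (("PP2",), "VUS"),
    (("PP3",), "VUS"),
    (("BP4",), "VUS"),
    (("PVS1", "PS2"), "Pathogenic"),
    (("PVS1", "PM2"), "Likely pathogenic"),
    (("PVS1", "PP2"), "VUS"),
    (("PVS1", "PP3"), "VUS"),
    (("PVS1", "BP4"), "VUS"),
    (("PS2", "PM2"), "Likely pathogenic"),
    (("PS2", "PP2"), "VUS"),
    (("PS2", "PP3"), "VUS"),
    (("PS2", "BP4"), "VUS"),
    (("PM2", "PP2"), "VUS"),
    (("PM2", "PP3"), "VUS"),
    (("PM2", "BP4"), "VUS"),
    (("PP2", "PP3"), "VUS"),
    (("PP2", "BP4"), "VUS"),
    (("PP3", "BP4"), "VUS"),
    (("PVS1", "PS2", "PM2"), "Pathogenic"),
    (("PVS1", "PS2", "PP2"), "Pathogenic"),
    (("PVS1", "PS2", "PP3"), "Pathogenic"),
    (("PVS1", "PS2", "BP4"), "VUS"),
    (("PVS1", "PM2", "PP2"), "Pathogenic"),
    (("PVS1", "PM2", "PP3"), "Pathogenic"),
    (("PVS1", "PM2", "BP4"), "VUS"),
    (("PVS1", "PP2", "PP3"), "Pathogenic"),
    (("PVS1", "PP2", "BP4"), "VUS"),
    (("PVS1", "PP3", "BP4"), "VUS"),
    (("PS2", "PM2", "PP2"), "Likely pathogenic"),
    (("PS2", "PM2", "PP3"), "Likely pathogenic"),
    (("PS2", "PM2", "BP4"), "VUS"),
    (("PS2", "PP2", "PP3"), "Likely pathogenic"),
    (("PS2", "PP2", "BP4"), "VUS"),
    (("PS2", "PP3", "BP4"), "VUS"),
    (("PM2", "PP2", "PP3"), "VUS"),
    (("PM2", "PP2", "BP4"), "VUS"),
    (("PM2", "PP3", "BP4"), "VUS"),
    (("PP2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PS2", "PM2", "PP2"), "Pathogenic"),
    (("PVS1", "PS2", "PM2", "PP3"), "Pathogenic"),
    (("PVS1", "PS2", "PM2", "BP4"), "VUS"),
    (("PVS1", "PS2", "PP2", "PP3"), "Pathogenic"),
    (("PVS1", "PS2", "PP2", "BP4"), "VUS"),
    (("PVS1", "PS2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PM2", "PP2", "PP3"), "Pathogenic"),
    (("PVS1", "PM2", "PP2", "BP4"), "VUS"),
    (("PVS1", "PM2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PP2", "PP3", "BP4"), "VUS"),
    (("PS2", "PM2", "PP2", "PP3"), "Likely pathogenic"),
    (("PS2", "PM2", "PP2", "BP4"), "VUS"),
    (("PS2", "PM2", "PP3", "BP4"), "VUS"),
    (("PS2", "PP2", "PP3", "BP4"), "VUS"),
    (("PM2", "PP2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PS2", "PM2", "PP2", "PP3"), "Pathogenic"),
    (("PVS1", "PS2", "PM2", "PP2", "BP4"), "VUS"),
    (("PVS1", "PS2", "PM2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PS2", "PP2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PM2", "PP2", "PP3", "BP4"), "VUS"),
    (("PS2", "PM2", "PP2", "PP3", "BP4"), "VUS"),
    (("PVS1", "PS2", "PM2", "PP2", "PP3", "BP4"), "VUS"),
]


def test_truth_table_is_exhaustive():
    assert len(TRUTH_TABLE) == 64
    assert len({frozenset(s) for s, _ in TRUTH_TABLE}) == 64


@pytest.mark.parametrize("codes,expected", TRUTH_TABLE,
                         ids=["+".join(c) or "empty" for c, _ in TRUTH_TABLE])
def test_combiner_matches_hand_enumerated_truth_table(codes, expected):
    criteria = CriteriaSet(frozenset(Code(c) for c in codes))
    assert combine_criteria(criteria).value == expected


def test_combiner_is_order_invariant():
    codes = ["PVS1", "PS2", "PM2", "PP2", "PP3"]
    tiers = {
        combine_criteria(CriteriaSet(frozenset(Code(c) for c in perm)))
        for perm in itertools.permutations(codes)
    }
    assert len(tiers) == 1


_RANK = {TierClass.VUS: 0, TierClass.LIKELY_PATHOGENIC: 1, TierClass.PATHOGENIC: 2}


def test_evidence_monotonicity():
    """Adding pathogenic-direction evidence never moves toward benign;
    adding BP4 never moves toward pathogenic."""
    pathogenic_codes = [Code.PVS1, Code.PS2, Code.PM2, Code.PP2, Code.PP3]
    for r in range(len(pathogenic_codes) + 1):
        for base in itertools.combinations(pathogenic_codes, r):
            base_set = frozenset(base)
            t0 = combine_criteria(CriteriaSet(base_set))
            for extra in pathogenic_codes:
                if extra in base_set:
                    continue
                t1 = combine_criteria(CriteriaSet(base_set | {extra}))
                assert _RANK[t1] >= _RANK[t0], (base_set, extra)
            t_b = combine_criteria(CriteriaSet(base_set | {Code.BP4}))
            assert _RANK[t_b] <= _RANK[t0], base_set


def test_unsupported_code_rejected():
    from triodnv.errors import ConfigurationError

    with pytest.raises(ConfigurationError):
        combine_criteria(CriteriaSet(frozenset({"PS1"})))  # type: ignore[arg-type]


def test_classify_variant_composition():
    result = classify_variant(_ann(Consequence.STOP_GAIN, lof_mech=True), None)
    assert result.criteria.codes == {Code.PVS1, Code.PS2, Code.PM2}
    assert result.tier is TierClass.PATHOGENIC
    gus = classify_variant(_ann(Consequence.STOP_GAIN, ndd=False), None)
    assert gus.criteria is None
    assert gus.tier is TierClass.VARIANT_OF_INTEREST_GUS
    nc = classify_variant(_ann(ndd=False), _calls("TTTT"))
    assert nc.tier is TierClass.NOT_CLASSIFIED


def test_policy_thresholds_are_configurable():
    strict = AssignmentPolicy(pp3_min_damaging=4)
    got = assign_criteria(_ann(), _calls("DDDT"), strict)
    assert Code.PP3 not in got.codes
    loose = AssignmentPolicy(pm2_max_maf=1e-4)
    got = assign_criteria(_ann(maf=3.2e-5), _calls("DDDD"), loose)
    assert Code.PM2 in got.codes
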