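import numpy as np
import pytest

from triodnv.annotation import Consequence, GeneConstraint, PredictorScores, VariantAnnotation
from triodnv.pipeline import classify_fixture_tables
from triodnv.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic cohort shared across tests."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_report():
    """Classification report for the shipped variant fixture tables."""
    return classify_fixture_tables()


def random_annotation(rng: np.random.Generator) -> VariantAnnotation:
    """A random annotation that straddles every cascade gate."""
    consequence = rng.choice(list(Consequence))
    gene = rng.choice(["GENEA", "GENEB", "BRCA2", "TP53", "GENEC"])
    constraint = None
    if rng.random() > 0.1:
        constraint = GeneConstraint(
            gene,
            pli=float(rng.choice([0.0, 0.85, 0.89, 0.9, 0.91, 0.99])),
            loeuf=float(rng.choice([0.1, 0.59, 0.6, 0.61, 1.2])),
            mis_z=float(rng.choice([0.0, 2.4, 2.5, 2.6, 4.0])),
        )
    scores = PredictorScores(
        mcap=float(rng.choice([0.01, 0.03])),
        revel=float(rng.choice([0.4, 0.6])),
        primateai=float(rng.choice([0.7, 0.9])),
        alphamissense=float(rng.choice([0.2, 0.45, 0.7])),
    )
    return VariantAnnotation(
        candidate=None,
        gene=str(gene),
        transcript_id="NM_TEST",
        consequence=consequence,
        maf=float(rng.choice([0.0, 1e-6, 1e-3])),
        constraint=constraint,
        scores=scores,
        ndd_gene=bool(rng.random() > 0.5),
        ndd_lof_mechanism=bool(rng.random() > 0.5),
        is_major_transcript=bool(rng.random() > 0.2),
        dist_to_transcript_end_bp=int(rng.choice([0, 30, 49, 50, 51, 500])),
        in_functional_domain=bool(rng.random() > 0.5),
        splice_canonical=bool(rng.random() > 0.5),
    )
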