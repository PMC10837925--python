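import numpy as np
import pytest

import oligoburden as ob


@pytest.fixture(scope="session")
def reference_cohort():
    """Deterministic cohort whose counts match the published tables."""
    return ob.reference_fixture()


@pytest.fixture(scope="session")
def reference_matrix(reference_cohort):
    return reference_cohort.carrier_matrix()


@pytest.fixture(scope="session")
def small_random_matrix():
    """A small stochastic cohort for oracle-recount tests."""
    panel = ob.GenePanel(
        entries={
            "GENE_A": "meiosis_dna_repair",
            "GENE_B": "meiosis_dna_repair",
            "GENE_C": "ovarian_development",
            "GENE_D": "signaling_transcription",
            "GENE_E": "gonadal_formation",
        }
    )
    cfg = ob.SyntheticConfig(
        n_cases=20, n_controls=40, panel=panel, control_carrier_prob=0.15,
        gene_or={"GENE_A": 4.0}, planted_pairs=(), decoy_rate=0.5, seed=11,
    )
    cohort = ob.generate_cohort(cfg)
    return cohort, cohort.carrier_matrix()


def random_variant(rng: np.random.Generator, gene: str = "GENE_A") -> ob.VariantRecord:
    """A variant with randomised filter attributes spanning all filter branches."""
    consequence = rng.choice(
        ["missense_variant", "frameshift_variant", "stop_gained",
         "splice_donor_variant", "synonymous_variant"]
    )
    maybe = lambda v: None if rng.random() < 0.3 else float(v)
    return ob.VariantRecord(
        chrom="1", pos=int(rng.integers(1, 10_000)), ref="A", alt="T", gene=gene,
        consequence=str(consequence), depth=int(rng.integers(1, 60)),
        af_gnomad=maybe(rng.uniform(0, 0.2)), af_exac=maybe(rng.uniform(0, 0.2)),
        af_1kg=maybe(rng.uniform(0, 0.2)), revel=maybe(rng.uniform(0, 1)),
        splice_score=maybe(rng.uniform(0, 1)), scsnv=maybe(rng.uniform(0, 1)),
    )
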