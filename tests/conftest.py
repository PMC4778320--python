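import pytest

from isoswitch.normalize import detect_isoforms, log2_transform, upper_quartile_normalize
from isoswitch.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted cohort shared by fast unit tests."""
    cfg = SimConfig(
        n_samples=150,
        n_genes=300,
        n_rin_artifacts=8,
        n_subtype_switches=10,
        n_bimodal_switches=3,
        n_signature_genes=40,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Normalized/log2 matrices and the detection result for the small cohort."""
    matrix, catalog, annot, truth = small_cohort
    normed = upper_quartile_normalize(matrix)
    logged = log2_transform(normed)
    det = detect_isoforms(normed, catalog)
    return normed, logged, det, catalog, annot, truth
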