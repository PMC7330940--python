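import pytest

from homoeosplice import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_bundle():
    """Error-free cohort: every downstream stage should recover truth exactly."""
    cfg = SimConfig(
        n_genes=20,
        seed=11,
        error_rate=0.0,
        het_snp_frac=0.0,
        outlier_snp_rate=0.0,
        depth=60.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-conditions cohort at reduced gene count for module tests."""
    cfg = SimConfig(n_genes=30, seed=7)
    return generate_cohort(cfg)
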