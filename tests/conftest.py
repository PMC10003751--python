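import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-family synthetic cohort shared by read-only tests."""
    from irdscape.simulate import FounderAllele, SimConfig, simulate_cohort
    from irdscape.model import VariantKind

    config = SimConfig(
        n_index=60,
        founder_alleles=(
            FounderAllele("EYS", 9, VariantKind.CNV_DEL),
            FounderAllele("ABCA4", 4, VariantKind.SNV),
        ),
        seed=11,
    )
    return config, simulate_cohort(config)
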