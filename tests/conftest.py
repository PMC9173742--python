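import pytest

from vtatrace.catalog import load_default_catalog
from vtatrace.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def cohort4(catalog):
    """Default-sized cohort: 4 brains at the study conditions."""
    return generate_cohort(GeneratorConfig(n_brains=4, seed=11), catalog)


@pytest.fixture(scope="session")
def cohort50(catalog):
    """Larger cohort for Monte-Carlo parameter-recovery checks."""
    return generate_cohort(GeneratorConfig(n_brains=50, seed=13), catalog)


@pytest.fixture(scope="session")
def cohort50_multinomial(catalog):
    """50 brains without planted covariance or jitter.

    Region counts are then exactly multinomial around the configured
    composition, which is the regime the binomial/multinomial recovery
    tolerances are computed for.
    """
    cfg = GeneratorConfig(
        n_brains=50, seed=17, archetype_strength=0.0, noise_scale=0.0
    )
    return generate_cohort(cfg, catalog)
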