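import numpy as np
import pytest

from methpanel.synthetic import (
    GeneratorConfig,
    generate_cohort,
    planted_panel,
    scale_counts,
)

PLANTED = frozenset({3, 12, 14, 18, 20, 21})


@pytest.fixture(scope="session")
def planted_cohort():
    """Small paired cohort (5% of the bundled design) with a strong planted panel."""
    cfg = GeneratorConfig(seed=11)
    cfg = scale_counts(cfg, 0.05)
    cfg = planted_panel(cfg, PLANTED, delta=2.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no tumor/normal effect anywhere (delta = 0)."""
    cfg = GeneratorConfig(seed=12, patient_sd=0.3)
    cfg = scale_counts(cfg, 0.05)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
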