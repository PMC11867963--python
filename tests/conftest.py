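import numpy as np
import pytest

from oncoscreen.synthetic_cohort import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with the default planted effects (d=1.5, slope=1.5,
    hazard_beta=0.4, rho=-0.5) at a size every test can afford."""
    return generate_cohort(
        SyntheticConfig(n_genes=300, n_tumor=150, n_normal=40, emt_set_size=50, seed=42)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every planted effect switched off."""
    return generate_cohort(
        SyntheticConfig.null(n_genes=400, n_tumor=200, n_normal=40, emt_set_size=50, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
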