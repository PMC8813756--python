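import numpy as np
import pytest

from placentadeconv import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy six-type cohort reused by read-only tests."""
    cfg = CohortConfig(n_samples=60, n_cpgs=800, n_markers=240, noise_sd=0.02, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisefree_cohort():
    cfg = CohortConfig(n_samples=40, n_cpgs=600, n_markers=180, noise_sd=0.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def three_component_cohort():
    """Well-separated 3-type mixture for reference-free recovery tests."""
    cfg = CohortConfig(
        n_samples=150, n_cpgs=600, n_markers=90, noise_sd=0.0,
        study_preset="custom", cell_types=("A", "B", "C"),
        custom_mean=(0.4, 0.35, 0.25), dirichlet_concentration=5.0, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
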