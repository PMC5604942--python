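import pytest

from snpqr.panel import load_bundled_panel


@pytest.fixture(scope="session")
def panel():
    return load_bundled_panel()


@pytest.fixture(scope="session")
def two_individuals(panel):
    """Two unrelated HWE-simulated genotype tables over the full panel."""
    from snpqr.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(panel, SimulationConfig(n_individuals=2, seed=20260927))
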