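import pytest

from neuroloc import SimConfig, analyze_bundle, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic experiment (2,000 genes, 3 reps)."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return analyze_bundle(default_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast 400-gene bundle for structural checks."""
    return simulate_bundle(SimConfig(n_genes=400, seed=7))
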