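import pytest
from hypothesis import HealthCheck, settings

from ambistop.scg import run_pipeline
from ambistop.synth import SyntheticConfig, generate_bundle

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_config() -> SyntheticConfig:
    """A reduced bundle for fast unit tests (same structure, fewer genes)."""
    return SyntheticConfig(
        seed=7,
        n_genes=40,
        n_nuclear_contigs=2,
        n_mito_contigs=3,
        mito_repeat_families=3,
        n_bacterial_contigs=1,
        n_host_contigs=1,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture(scope="session")
def small_run(small_bundle):
    b = small_bundle
    return run_pipeline(b.genome, b.annotation, b.proteome, b.transcripts)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study conditions (seed 42, ~600 genes)."""
    return generate_bundle(SyntheticConfig())


@pytest.fixture(scope="session")
def default_run(default_bundle):
    b = default_bundle
    return run_pipeline(b.genome, b.annotation, b.proteome, b.transcripts)
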