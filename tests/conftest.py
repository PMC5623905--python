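import pytest

from varstruct.pipeline import RunConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Small synthetic study shared by read-only tests."""
    return generate_study(n_genes=4, seed=11)


@pytest.fixture(scope="session")
def config():
    return RunConfig(bootstrap_B=200, n_perm=2000, seed=11)
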