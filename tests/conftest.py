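import pytest

from tisnet import study, synthetic


@pytest.fixture(scope="session")
def small_config():
    """A small but complete synthetic study configuration."""
    return synthetic.GeneratorConfig(
        n_genes=400,
        n_diseases=30,
        expression_effect=1.5,
        n_planted_ts_edges=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Fully assembled small study: expressomes, networks, disease panel."""
    return study.assemble(small_config)
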