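import pytest

from nanoforesight import GeneratorConfig, generate, load_packaged_regdb


@pytest.fixture(scope="session")
def default_db():
    """Synthetic signal database under the default study conditions, seed 1."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def regdb():
    """The packaged nine-document regulatory table."""
    return load_packaged_regdb()
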