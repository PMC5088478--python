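import pytest

from amdvalue.params import ModelParameters, load_parameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Base-case parameter registry."""
    return load_parameters()
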