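import pytest

from anemecon.parameters import default_parameters


@pytest.fixture
def base_params():
    return default_parameters()
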