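import pytest

from td_arousal import ModelParams


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def fast_params():
    """Defaults with the moderate-training arousal decay used in most
    figure reproductions."""
    return ModelParams(eta=0.97)
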