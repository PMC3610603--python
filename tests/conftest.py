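from dataclasses import replace

import pytest

from rivalnorm import ModelParams, NoiseParams


@pytest.fixture
def params() -> ModelParams:
    """Default (Table-1-style) opponency/conventional parameters."""
    return ModelParams()


@pytest.fixture
def quiet_params() -> ModelParams:
    """Parameters with the noise switched off (deterministic dynamics)."""
    return ModelParams(noise=NoiseParams(amplitude=0.0))


@pytest.fixture
def adapt_params() -> ModelParams:
    return replace(ModelParams(), adapt_enabled=True)
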