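import numpy as np
import pytest

from eugnet import SceneConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 32x32 scenes — enough for smoke-level training tests."""
    return generate_dataset(SceneConfig(height=32, width=32, n_tools=1,
                                        tool_length_range=(20, 30),
                                        tool_width_range=(3, 6), seed=42), 8)
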