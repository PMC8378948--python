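import numpy as np
import pytest
from hypothesis import settings

from taskcrnn.model import ConvBlockConfig, CrnnConfig
from taskcrnn.preprocess import BlockClip

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

# tiny spatial grid used by fast unit tests (full-size ops are exercised
# analytically or on zeros; allocating real full-size runs is pointless here)
TINY_SPATIAL = (4, 5, 3)


def micro_crnn_config(
    spatial=(8, 10, 8), t=20, lstm_units=8, n_classes=7, dropout=0.2
) -> CrnnConfig:
    """A minimal but structurally faithful CRNN: strided block + full conv."""
    from taskcrnn.nn import conv_output_size

    k1 = (3, 3, 3)
    mid = tuple(conv_output_size(n, k, 2) for n, k in zip(spatial, k1))
    return CrnnConfig(
        conv_blocks=(ConvBlockConfig(k1, 4, 2), ConvBlockConfig(mid, 8, 1)),
        lstm_units=lstm_units,
        lstm_dropout=dropout,
        attention_dim=8,
        dense_units=8,
        n_classes=n_classes,
        input_shape=(t, *spatial, 1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_clip(rng):
    """One 36-frame block clip on a tiny grid."""
    data = rng.gamma(2.0, 50.0, size=(*TINY_SPATIAL, 36)).astype(np.float32)
    return BlockClip(data=data, subject_id="sub-001", task_name="Emotion")
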