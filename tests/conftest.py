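import numpy as np
import pytest

from midecode import EEGEpochSet, ModelConfig
from midecode.synthetic import SyntheticSpec, default_signatures


@pytest.fixture
def tiny_cfg():
    """Smallest architecture that exercises every stage (seq len 4, 3 windows)."""
    return ModelConfig(C=3, T=256, Nc=2, F1=8, D=2)


@pytest.fixture
def tiny_spec():
    """Cheap high-SNR 2-class generator matched to tiny_cfg's geometry."""
    sigs = default_signatures(2, 3, modulation_depth=0.8)
    return SyntheticSpec(
        trials_per_class=12, class_signatures=sigs, n_subjects=3,
        n_channels=3, fs=250.0, epoch_duration=1.024, n_classes=2,
        noise_sd=0.5, seed=7,
    )


@pytest.fixture
def random_epochs():
    """Unstructured noise epochs for shape/metadata tests."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((20, 4, 128)).astype(np.float32)
    labels = np.tile(np.arange(4), 5)
    return EEGEpochSet(data, labels, fs=128.0,
                       channel_names=[f"CH{i}" for i in range(4)],
                       subject_id="T01", n_classes=4)
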