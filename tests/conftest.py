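import numpy as np
import pytest

from mseeg import CohortSpec, EntropyConfig, generate_cohort
from mseeg.preprocessing import segment_epochs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cfg():
    return EntropyConfig()


@pytest.fixture(scope="session")
def small_cohort_epochs():
    """Epochs of a small synthetic cohort with a scale-3 group contrast.

    4 + 4 subjects, 3 channels, 30 s each -> 24 epochs (12 per class).
    Session-scoped: entropy extraction over these epochs is the expensive
    part of several tests.
    """
    spec = CohortSpec(n_hc=4, n_mdd=4, n_channels=3, duration=30.0,
                      effect_scale=3, effect_size=0.6, seed=77)
    epochs = []
    for rec in generate_cohort(spec):
        epochs.extend(segment_epochs(rec, 10.0))
    return spec, epochs
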