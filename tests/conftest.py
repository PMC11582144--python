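import numpy as np
import pytest

import sadfmri as sf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_training_run():
    """One semi-supervised run on well-separated synthetic data.

    Strong 2% responses with wide latency jitter, a fixed 10% tail fraction
    and enough epochs for the compact network to converge; shared by the
    loop-recovery and the SAD-vs-GLM discordance tests.
    """
    data = sf.generate(sf.SyntheticSpec(n_active=150, n_baseline=1350,
                                        amplitude_pct=2.0, latency_sd=0.5, seed=5))
    cfg = sf.TrainConfig(seed=0, max_iterations=3, epochs=100, per_class_add=50,
                         alpha=0.10, allow_unsafe_confidence=True)
    result = sf.run_sad(data.series, cfg)
    return data, cfg, result
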