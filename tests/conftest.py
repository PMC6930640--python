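import numpy as np
import pytest

from fpqsar import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strong_signal_data():
    """Small dataset with a strong additive signal (oracle R2 = 0.8)."""
    spec = synthetic.SyntheticSpec(
        n_compounds=200,
        n_features=20,
        informative_idx=[0, 1, 2],
        coefficients=[0.4, 0.4, 0.4],
        noise_sd=0.0,
        seed=42,
    )
    X = synthetic.generate_fingerprint_matrix(spec)
    spec.noise_sd = synthetic.noise_sd_for_r2(X, spec, 0.8)
    y = synthetic.generate_activity(X, spec)
    return X, y, spec
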