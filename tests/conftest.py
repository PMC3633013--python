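import numpy as np
import pytest

from beauwalk import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def best_fit():
    """Best-fitting microscopic triplet: t_pause=0.5, t_free=2.0, v_free=18.8."""
    return ModelParams(0.5, 2.0, 18.8)


def variance_se(samples: np.ndarray) -> float:
    """Moment-based standard error of a sample variance."""
    n = samples.size
    c = samples - samples.mean()
    m2 = np.mean(c**2)
    m4 = np.mean(c**4)
    return float(np.sqrt(max(m4 - m2**2, 0.0) / n))
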