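import numpy as np
import pytest

from promsig import SyntheticSpec, generate
from promsig.motifs import PWM, BackgroundModel


@pytest.fixture(scope="session")
def uniform_bg() -> BackgroundModel:
    return BackgroundModel()


@pytest.fixture(scope="session")
def sharp_pwm() -> PWM:
    """8-mer with a 0.97-dominant base per position (consensus ACGTACGT)."""
    probs = np.full((8, 4), 0.01)
    for i, base in enumerate([0, 1, 2, 3, 0, 1, 2, 3]):
        probs[i, base] = 0.97
    return PWM("sharp8", probs)


@pytest.fixture(scope="session")
def small_bundle():
    """Small but complete synthetic dataset (30 high / 30 low genes)."""
    return generate(SyntheticSpec(n_high=30, n_low=30, n_other=5, seed=11))


def random_pwm(rng: np.random.Generator, length: int, motif_id: str = "m") -> PWM:
    probs = rng.dirichlet(np.full(4, 0.5), size=length)
    probs = np.clip(probs, 1e-3, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(motif_id, probs)
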