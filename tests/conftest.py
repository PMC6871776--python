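import numpy as np
import pytest

from quadrugait.morphology import GaitTask, Morphology


@pytest.fixture
def dalmatian() -> Morphology:
    return Morphology(mF_prime=0.61, lB=0.61, lHmax_prime=0.89, lFmax_prime=0.79)


@pytest.fixture
def dalmatian_task(dalmatian) -> GaitTask:
    return GaitTask.from_speed(dalmatian, U_H_prime=0.39, D_prime=1.21)


@pytest.fixture
def malinois() -> Morphology:
    return Morphology(mF_prime=0.63, lB=0.48, lHmax_prime=1.01, lFmax_prime=0.92)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_configuration(rng, morph, n=1):
    """Random body states, forces and feet for kernel-level checks."""
    x = rng.uniform(-1, 2, n)
    y = rng.uniform(0.3, 1.2, n)
    th = rng.uniform(-0.5, 0.5, n)
    vx = rng.uniform(-2, 3, n)
    vy = rng.uniform(-1, 1, n)
    om = rng.uniform(-2, 2, n)
    F = rng.uniform(0, 3, (n, 7))
    feet = x[:, None] + rng.uniform(-1.0, 1.0, (n, 7))
    return x, y, th, vx, vy, om, F, feet
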