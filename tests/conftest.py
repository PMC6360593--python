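"""Shared fixtures: random SPD instances and session-scoped synthetic sets."""

import numpy as np
import pytest

import riemannmi as rm
from riemannmi import spd


def random_spd(rng: np.random.Generator, n: int, cond_max: float = 1e3) -> np.ndarray:
    """Random SPD matrix with bounded condition number."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    lo = 1.0 / np.sqrt(cond_max)
    hi = np.sqrt(cond_max)
    w = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return (Q * w) @ Q.T


def random_symmetric(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    A = rng.standard_normal((n, n)) * scale
    return 0.5 * (A + A.T)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_set():
    """High-separation 4-class benchmark: 8 channels, 100 trials/class, df 200."""
    cfg = rm.synthetic.GeneratorConfig(seed=11)
    return rm.synthetic.generate_trials(cfg)


@pytest.fixture(scope="session")
def benchmark_covs(benchmark_set):
    return spd.compute_scms(benchmark_set.X)


@pytest.fixture(scope="session")
def zero_sep_set():
    """Same benchmark conditions but separation 0: all classes identical."""
    cfg = rm.synthetic.GeneratorConfig(seed=11, separation=0.0)
    return rm.synthetic.generate_trials(cfg)
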