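import numpy as np
import pytest

import banzhafselect as bs


@pytest.fixture(scope="session")
def short_records():
    """Six synthetic 8-second 3-channel records (short for speed; the
    DWT's boundary extension handles any length)."""
    spec = bs.WaveformSpec(n_records=6, duration_s=8.0, fs=250.0, seed=7)
    return bs.synth_vital_records(spec)


@pytest.fixture(scope="session")
def benchmark_table():
    """One replicate of the XOR synergy benchmark table plus roles."""
    return bs.synth_feature_table(bs.TabularSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_interdependency(n: int, seed: int, scale: float = 0.1) -> np.ndarray:
    """Random interdependency matrix with zero diagonal."""
    r = np.random.default_rng(seed)
    D = r.normal(0.0, scale, (n, n))
    np.fill_diagonal(D, 0.0)
    return D
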