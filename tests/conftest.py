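import numpy as np
import pytest

from octsex.engine import ScanConfig, SourceSpectrum
from octsex.phantom import CohortSpec, PhantomParams


@pytest.fixture(scope="session")
def source():
    return SourceSpectrum()


@pytest.fixture(scope="session")
def small_source():
    """Reduced spectral sampling for fast simulator tests."""
    return SourceSpectrum(n_spectral_samples=512)


@pytest.fixture(scope="session")
def small_scan():
    """Coarse scan grid matching the reduced spectral sampling."""
    return ScanConfig(n_alines=120, depth_pixels=200, depth_crop=120, depth_pitch_um=20.0)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    return CohortSpec(n_chicks=4, frames_per_chick=6, keep_per_chick=5, ambiguous_rate=0.0, seed=3)


@pytest.fixture(scope="session")
def separable_images():
    """Trivially separable toy set: bright left half vs bright right half."""
    rng = np.random.default_rng(0)
    n = 40
    X = (rng.random((n, 32, 32)) * 0.2).astype(np.float32)
    y = np.array(["female", "male"] * (n // 2))
    for i in range(n):
        if y[i] == "male":
            X[i, :, :16] += 0.6
        else:
            X[i, :, 16:] += 0.6
    return X, y
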