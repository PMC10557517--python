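import numpy as np
import pytest

from mhcluster.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort():
    """Small labeled cohort (4 colleges x 30) — fast but still 4 separable grades."""
    return generate_cohort(CohortConfig(n_colleges=4, n_per_college=30, seed=7))


@pytest.fixture
def zero_noise_cohort():
    """Degenerate cohort whose records coincide exactly with the grade profiles."""
    return generate_cohort(CohortConfig(n_colleges=2, n_per_college=40, noise_sd=0.0, seed=3))


def make_blobs(rng, centers, n_per, spread):
    """Isotropic Gaussian blobs around the given centers (simple planted data)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    data, labels = [], []
    for i, c in enumerate(centers):
        data.append(c + rng.normal(0.0, spread, size=(n_per, centers.shape[1])))
        labels.extend([i] * n_per)
    return np.vstack(data), np.array(labels)
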