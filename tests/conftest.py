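import numpy as np
import pytest

import mristand as ms


@pytest.fixture(scope="session")
def default_phantom():
    """Noisy 64^3 phantom with ground-truth labels (seed 1)."""
    spec = ms.PhantomSpec(seed=1)
    vol, labels = ms.generate_phantom(spec)
    return spec, vol, labels


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Three-level phantom: every tissue voxel at its exact mean."""
    spec = ms.PhantomSpec(tissue_sds={"CSF": 0.0, "GM": 0.0, "WM": 0.0}, seed=1)
    vol, labels = ms.generate_phantom(spec)
    return spec, vol, labels


@pytest.fixture(scope="session")
def phantom_histogram(default_phantom):
    _, vol, _ = default_phantom
    return ms.compute_histogram(vol)


def two_gaussian_histogram(
    n_voxels=2_400_000, gm_mode=1907.0, wm_mode=3246.0,
    gm_sd=75.9, wm_sd=58.5, gm_fraction=0.55, seed=0,
):
    """Poisson-sampled histogram of a two-Gaussian tissue mixture."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    levels = np.arange(4096)
    p = (gm_fraction * stats.norm.pdf(levels, gm_mode, gm_sd)
         + (1 - gm_fraction) * stats.norm.pdf(levels, wm_mode, wm_sd))
    counts = rng.poisson(n_voxels * p)
    return ms.IntensityHistogram(np.arange(4097, dtype=float), counts)
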