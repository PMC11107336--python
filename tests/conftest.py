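import numpy as np
import pytest

import fiberscope as fs


@pytest.fixture(scope="session")
def bundle790():
    """Full-scale bundle: 790 um FOV, 4.5 um pitch (built once, geometry cached)."""
    return fs.build_bundle()


@pytest.fixture(scope="session")
def seq790():
    return fs.make_scan_sequence(790)


@pytest.fixture(scope="session")
def phantom1():
    """Default epithelium phantom, seed 1."""
    return fs.default_phantom(seed=1)


@pytest.fixture(scope="session")
def bundle300():
    """Reduced-FOV bundle for fast multi-seed tests."""
    return fs.build_bundle(300.0)


@pytest.fixture(scope="session")
def seq300():
    return fs.make_scan_sequence(300)


@pytest.fixture(scope="session")
def small_phantom():
    """Phantom covering the 300 um bundle, default tissue conditions."""
    return fs.default_phantom(seed=11, field_extent_um=330.0)


@pytest.fixture
def noise_free():
    """Acquisition overrides that disable every stochastic term."""
    return dict(shot_noise=False, read_noise_sd=0.0, rng_seed=0)


def brute_force_pairwise_min(centers: np.ndarray) -> float:
    """O(n^2) oracle for the minimum pairwise distance."""
    n = len(centers)
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(centers[i, 0] - centers[j, 0],
                         centers[i, 1] - centers[j, 1])
            best = min(best, d)
    return best
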