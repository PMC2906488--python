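import numpy as np
import pytest

from mklfuse import KernelMatrix, KernelSet, generate_fusion_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kernel(rng, n: int, d: int = 4, name: str = "k") -> KernelMatrix:
    X = rng.normal(size=(n, d))
    return KernelMatrix(X @ X.T + 1e-8 * np.eye(n), None, name)


@pytest.fixture
def psd_pair(rng) -> KernelSet:
    """Two random PSD kernels over 12 shared samples."""
    return KernelSet([random_psd_kernel(rng, 12, 3, "a"),
                      random_psd_kernel(rng, 12, 5, "b")])


@pytest.fixture
def toy_fusion():
    """Small binary fusion dataset: 2 informative + 1 noise view, N = 60."""
    ds = generate_fusion_dataset(n_samples=60, informative=(2.0, 1.2),
                                 n_noise_views=1, n_features=6, seed=42)
    return ds, ds.kernel_set()
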