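import numpy as np
import pytest

from texfuse.synthetic import SpeckleParams, build_benchmark_dataset


@pytest.fixture(scope="session")
def small_benchmark():
    """100 patches per class at the default class parameters, fixed master seed."""
    return build_benchmark_dataset(100, seed=11)


@pytest.fixture(scope="session")
def tiny_patch_pair():
    """Two deterministic small patches (one per class) for cheap operator tests."""
    from texfuse.synthetic import simulate_speckle_patch

    hcc = simulate_speckle_patch(SpeckleParams(class_label="HCC", seed=5))
    par = simulate_speckle_patch(
        SpeckleParams(class_label="PAR", correlation_length_px=1.2,
                      heterogeneity_blob_count=1, heterogeneity_blob_contrast=0.15,
                      seed=6))
    return hcc, par


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
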