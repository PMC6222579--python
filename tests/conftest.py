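import numpy as np
import pytest

import omisurv as ov


@pytest.fixture(scope="session")
def small_dataset():
    """A small linked clinical + two-omic dataset with survival outcomes."""
    cfg = ov.SimConfig(
        n_patients=120,
        features_per_omic={"methylation": 300, "expression": 200},
        true_variance_components={"methylation": 0.5, "expression": 0.3},
        residual_variance=0.4,
        fixed_effects={"age": -0.02, "temozolomide": 0.35},
        seed=2024,
    )
    return ov.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_kernels(small_dataset):
    return ov.build_kernels(dict(small_dataset.omics))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
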