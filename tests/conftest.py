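import numpy as np
import pytest

import lbcreg as L


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_dataset():
    """120-point noisy 1D dataset, enough for quick training smoke tests."""
    return L.generate_synthetic_1d(120, L.NoiseSpec(base_scale=0.1), seed=4)


@pytest.fixture(scope="session")
def quick_emulator():
    """A small but genuinely trained emulator shared by interval,
    reporting and persistence tests (seconds, not minutes)."""
    data = L.generate_synthetic_1d(300, L.NoiseSpec(base_scale=0.1), seed=9)
    config = L.LbCConfig(
        outer_iterations=40,
        seed=3,
        hidden_widths=(32,),
        lr_predictor=1e-3,
        lr_interval=1e-4,
        data_split_mode="shared",
    )
    return L.train_lbc(data, config), data
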