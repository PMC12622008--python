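import numpy as np
import pandas as pd
import pytest

from tlsniche.config import SimConfig
from tlsniche.synthetic import generate_tissue, gradient_recovery_config


@pytest.fixture(scope="session")
def small_tissue():
    """Compact tissue with 2 TLS, 2 bronchi, 1 vessel for fast module tests."""
    cfg = SimConfig(
        field_width=1600.0,
        field_height=1600.0,
        n_tls=2,
        n_bronchi=2,
        n_vessels=1,
        seed=7,
    )
    return cfg, generate_tissue(cfg)


@pytest.fixture(scope="session")
def recovery_tissue():
    """CD4-rich tissue at the canonical gradient parameters (a=20, lam=100, b=1)."""
    cfg = gradient_recovery_config(seed=1)
    return cfg, generate_tissue(cfg)


@pytest.fixture()
def random_cells():
    """Factory for random cell tables used against brute-force oracles."""

    def make(n: int, seed: int, types=("A", "B", "C"), extent: float = 1000.0):
        rng = np.random.default_rng(seed)
        cells = pd.DataFrame(
            {
                "cell_id": [f"r{i:04d}" for i in range(n)],
                "x_um": rng.uniform(0, extent, n),
                "y_um": rng.uniform(0, extent, n),
                "cell_type": rng.choice(list(types), n),
            }
        ).set_index("cell_id", drop=False)
        return cells

    return make
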