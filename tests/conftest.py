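import numpy as np
import pytest

from neurocca import SyntheticConfig, generate, null_config
from neurocca.synthetic import _strength_for_rho


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def planted_bundle():
    """One strong planted mode (rho = 0.8), modest size, with confounds,
    missingness and near-constant items."""
    a = _strength_for_rho(0.8)
    cfg = SyntheticConfig(
        n_subjects=200, p_brain=40, q_behaviour=30, k_modes=1,
        a_x=(a,), a_y=(a,), n_near_constant=4, missing_rate=0.05, seed=42,
    )
    bundle, truth = generate(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def null_bundle():
    """No shared latent signal (K = 0)."""
    cfg = null_config(
        SyntheticConfig(n_subjects=150, p_brain=30, q_behaviour=25, seed=7)
    )
    bundle, truth = generate(cfg)
    return cfg, bundle, truth
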