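import warnings

import numpy as np
import pytest

from stemgrowth.synthetic import SimulationConfig, simulate_study

warnings.filterwarnings("ignore", category=RuntimeWarning, module="stemgrowth")


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimulationConfig(
        seed=1234,
        n_donors=80,
        n_common_variants=400,
        n_rare_variants=400,
        n_genes_rare=40,
        n_twin_pairs=4,
        h2_true=0.6,
        wells_per_donor=4,
        n_expr_genes=200,
        de_fraction=0.1,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
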