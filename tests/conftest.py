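import numpy as np
import pandas as pd
import pytest

from phenoprior import SimulationConfig, simulate_study


def small_sim_config(seed=0, **overrides):
    """Down-scaled simulation settings for fast structural tests."""
    params = dict(
        seed=seed,
        n_genes=120,
        n_training=10,
        n_case=50,
        n_background=50,
        mean_category_size=10,
        training_odds_multiplier=8.0,
        n_risk_genes=3,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study, shared across tests (read-only)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture()
def toy_gene_models():
    return pd.DataFrame(
        {
            "gene": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [50, 150, 200, 100],
            "end": [100, 160, 300, 200],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
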