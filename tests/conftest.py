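import numpy as np
import pandas as pd
import pytest

import glucovar as gv


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_panel():
    """Seven-population panel, scaled down for fast tests."""
    cfg = gv.SimulationConfig(
        population_names=("IND-LLA", "IND-NLLA", "AFR", "AMR", "EAS", "EUR", "SAS"),
        population_sizes=(5, 20, 30, 30, 30, 30, 30),
        n_variants=60,
        fst_per_population=0.1,
        missing_rate=0.02,
        seed=11,
    )
    gm, annotations = gv.simulate_panel(cfg)
    return cfg, gm, annotations


@pytest.fixture(scope="session")
def small_af_table(small_panel):
    _, gm, _ = small_panel
    return gv.allele_frequency_table(gm)


def toy_af_table(rows):
    """Build an allele table from (variant, population, alt, called) tuples."""
    return pd.DataFrame(
        rows, columns=["variant", "population", "alt_count", "called_alleles"]
    )
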