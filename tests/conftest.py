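import numpy as np
import pandas as pd
import pytest

from admixpress.config import SimConfig
from admixpress import simulate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=2,
        sites_per_chromosome=2000,
        fixed_diff_fraction=0.3,
        mean_dna_depth=30,
        n_segregants=3,
        crossovers_per_chromosome=1.0,
        n_genes=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A complete small synthetic study: panels, segregants, expression."""
    panel_a, panel_b, site_map = simulate.simulate_panels(small_config)
    mosaics = {}
    genotypes = {}
    for i in range(small_config.n_segregants):
        mosaic, geno = simulate.simulate_segregant(site_map, small_config, i)
        mosaics[mosaic.segregant] = mosaic
        genotypes[mosaic.segregant] = geno
    genes = simulate.simulate_gene_models(small_config)
    expr = simulate.simulate_expression(small_config, genes, mosaics, site_map)
    return {
        "config": small_config,
        "panel_a": panel_a,
        "panel_b": panel_b,
        "site_map": site_map,
        "mosaics": mosaics,
        "genotypes": genotypes,
        "genes": genes,
        "expr": expr,
    }


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(11)
    counts = rng.integers(0, 400, size=(50, 4)) + 1
    return pd.DataFrame(
        counts,
        index=[f"G{i}" for i in range(50)],
        columns=["A_1", "A_2", "B_1", "B_2"],
    )
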