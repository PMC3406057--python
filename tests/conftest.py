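import math

import numpy as np
import pytest

from pooledseq.synthetic_data import (
    PoissonDepth,
    PoolDesign,
    StrainPanel,
    draw_contributions,
    generate_panel,
    simulate_pool_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """22-strain uniform-SFS panel with source-population truth."""
    return generate_panel(22, 5000, sfs="uniform", seed=7)


@pytest.fixture
def private_panel():
    """21-strain panel of pure private SNPs: 100 sites per strain, carried
    by exactly that strain (identity-block genotypes)."""
    n_strains, per_strain = 21, 100
    n_sites = n_strains * per_strain
    genotypes = np.zeros((n_strains, n_sites), dtype=np.int8)
    for i in range(n_strains):
        genotypes[i, i * per_strain : (i + 1) * per_strain] = 1
    return StrainPanel(
        genotypes=genotypes,
        site_ids=np.array([f"s{j}" for j in range(n_sites)]),
        truth_freq=genotypes.mean(axis=0),
    )


@pytest.fixture
def equal_pool_counts(small_panel):
    design = PoolDesign(
        weights=draw_contributions(22, math.inf),
        depth_model=PoissonDepth(20),
        error_rate=0.0,
        min_depth=10,
    )
    return simulate_pool_reads(small_panel, design, seed=11, library_id="eq")
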