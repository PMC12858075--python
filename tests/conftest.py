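import numpy as np
import pytest

import pleioprs as p
from pleioprs.priors import PriorConfig, sample_mixture


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small no-overlap scenario shared across test modules."""
    cfg = p.SimulationConfig(
        m=300, n1=1200, n2=1200, ns=0, n_validation=300, n_test=400,
        n_panel=400, ld_block_size=30,
    )
    return p.run_scenario("no_overlap", cfg=cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_pair_blocks(tiny_scenario):
    """Harmonized pair + LD blocks derived from the tiny scenario."""
    b = tiny_scenario
    pair = p.harmonize(b.ss1, b.ss2, b.panel)
    panel_h = b.panel.subset_snps(pair.panel_index)
    part = p.BlockPartition(
        blocks=[(s, min(s + 30, pair.m)) for s in range(0, pair.m, 30)]
    )
    blocks = p.compute_block_ld(panel_h, part)
    return pair, blocks


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_mixture(rng):
    """A fixed draw of mixture parameters at low truncation."""
    return sample_mixture(PriorConfig(K=6), rng)
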