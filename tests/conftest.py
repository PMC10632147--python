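import numpy as np
import pytest

from epidriver.simulate import SimConfig, simulate_multiome


@pytest.fixture(scope="session")
def small_sim():
    """A compact multiome used by several suites (deterministic, seed 0)."""
    cfg = SimConfig(
        seed=0,
        cells_per_type=60,
        n_peaks=400,
        n_genes=120,
        n_planted_links=8,
        n_regulons=2,
        targets_per_regulon=20,
    )
    data, gt = simulate_multiome(cfg)
    return cfg, data, gt


@pytest.fixture(scope="session")
def link_scale_sim():
    """Multiome at the scale used for link-recovery checks:
    2,000 cells, 5,000 peaks, 1,000 genes, 50 planted links, effect 2.0."""
    cfg = SimConfig(
        seed=11,
        cells_per_type=400,
        n_peaks=5000,
        n_genes=1000,
        n_planted_links=50,
        link_effect=2.0,
    )
    data, gt = simulate_multiome(cfg)
    return cfg, data, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
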