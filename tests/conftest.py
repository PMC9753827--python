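import numpy as np
import pandas as pd
import pytest

from haplogp.genio import MAP_COLUMNS, HaplotypePanel
from haplogp.simdata import SimConfig, simulate_panel


def panel_from_haplotypes(hap, chrom=None, positions=None):
    """Build a HaplotypePanel directly from a (2n × m) 0/1 matrix."""
    hap = np.asarray(hap, dtype=np.int8)
    m = hap.shape[1]
    chrom = chrom if chrom is not None else ["1"] * m
    positions = positions if positions is not None else list(range(100, 100 + 100 * m, 100))
    mm = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"m{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["B"] * m,
        }
    )[MAP_COLUMNS]
    ids = [f"s{i}" for i in range(hap.shape[0] // 2)]
    return HaplotypePanel(hap, ids, mm)


@pytest.fixture(scope="session")
def sim_panel():
    """Mid-sized LD-structured panel shared across read-only tests."""
    cfg = SimConfig(
        n_individuals=200,
        n_chromosomes=2,
        markers_per_chrom=150,
        n_founders=60,
        n_generations=3,
        seed=42,
    )
    return simulate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
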