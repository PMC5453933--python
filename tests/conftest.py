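import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles importable

from dupmeth.simulate import SimulationConfig, generate_study


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        n_chromosomes=4,
        genes_per_chromosome=80,
        category_counts={"WGD": 12, "tandem": 8, "proximal": 8, "transposed": 10},
        wgd_block_size=6,
        sites_per_gene={"CG": 30, "CHG": 20, "CHH": 30},
        n_decoy_hits=300,
        cds_codons=100,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def study(sim_config):
    """One small synthetic study shared across the suite."""
    catalog, truth, hits, cx_wt, cx_mut, expr, cds = generate_study(sim_config)
    return {
        "config": sim_config, "catalog": catalog, "truth": truth, "hits": hits,
        "cx_wt": cx_wt, "cx_mut": cx_mut, "expr": expr, "cds": cds,
    }
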