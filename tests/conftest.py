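import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import recshift as rs

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def desk_panel():
    """Desk-scale founder panel: 200 haplotypes, 2 chromosomes x 1e6 bp."""
    return rs.synthesize_founders(rs.FounderConfig.desk(seed=7))


@pytest.fixture(scope="session")
def desk_map(desk_panel):
    """Scenario-2 map, 100 regions per chromosome (10 hotspots each)."""
    return rs.build_region_map(100, 2, desk_panel.chromosome_length_bp, desk_panel.n_chromosomes)


@pytest.fixture(scope="session")
def desk_arch(desk_panel, desk_map):
    return rs.sample_qtn(desk_panel, desk_map, 100, seed=11)


def make_population(tbvs, sexes, site_positions=None, haplotypes=None, length=1000):
    """Minimal Population for selection/pedigree tests (genotypes optional)."""
    n = len(tbvs)
    if haplotypes is None:
        haplotypes = [np.zeros((n, 2, 1), dtype=np.uint8)]
        site_positions = [np.array([0])]
    return rs.Population(
        haplotypes=haplotypes,
        site_positions=site_positions,
        chromosome_length_bp=length,
        sex=np.asarray(sexes, dtype=np.int8),
        ids=np.arange(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        tbv=np.asarray(tbvs, dtype=float),
        generation=0,
    )
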