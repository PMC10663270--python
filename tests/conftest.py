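import numpy as np
import pytest

from rggsim import genome
from rggsim.phenotypes import ScenarioConfig
from rggsim.program import desk_scale_config, run_program


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    return genome.build_genetic_map(n_chrom=5, total_cM=500.0,
                                    loci_per_chrom_range=(20, 30), n_qtl=40,
                                    rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def founders(small_map):
    return genome.simulate_founders(60, small_map, maf_min=0.05,
                                    rng=np.random.default_rng(8))


@pytest.fixture(scope="session")
def tiny_program():
    """One small selection program reused across integration tests."""
    cfg = desk_scale_config(ScenarioConfig.preset("A1"), years=18, seed=42,
                            family_size_range=(10, 14), location_pool=10)
    return run_program(cfg)


@pytest.fixture(scope="session")
def tiny_program_b2r():
    cfg = desk_scale_config(ScenarioConfig.preset("B2-R"), years=18, seed=43,
                            family_size_range=(10, 14), location_pool=10)
    return run_program(cfg)
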