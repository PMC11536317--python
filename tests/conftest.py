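import numpy as np
import pytest

from magicqtl.simulate import (
    FieldDesign,
    SimulationConfig,
    TraitSpec,
    simulate_founders,
    simulate_magic_rils,
)


@pytest.fixture(scope="session")
def small_pop():
    """120 MAGIC RILs on 3 chromosomes x 50 loci (seed 11)."""
    rng = np.random.default_rng(11)
    cfg = SimulationConfig(n_rils=120, n_chrom=3, loci_per_chrom=50)
    gmap = cfg.make_map()
    founders = simulate_founders(cfg, gmap, rng)
    return simulate_magic_rils(founders, cfg, rng), cfg, gmap


@pytest.fixture(scope="session")
def mid_pop():
    """200 MAGIC RILs on 3 chromosomes x 100 loci (seed 23), for GWAS tests."""
    rng = np.random.default_rng(23)
    cfg = SimulationConfig(n_rils=200, n_chrom=3, loci_per_chrom=100)
    gmap = cfg.make_map()
    founders = simulate_founders(cfg, gmap, rng)
    return simulate_magic_rils(founders, cfg, rng), cfg, gmap


@pytest.fixture
def lattice_design():
    return FieldDesign(environments=["2017.inf", "2018.inf"], replicates=2, block_size=8)


@pytest.fixture
def ivs_tunnel_trait():
    return TraitSpec.from_preset("ivs", "tunnel_length")
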