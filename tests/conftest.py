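import numpy as np
import pytest

from organphylo.genome_io import extract_region_sets
from organphylo.simulate import build_fixture, hotspot_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def hotspot_fixture():
    """Six simulated strains with three planted high-rate regions (shared across
    tests; deterministic)."""
    cfg = hotspot_config(seed=1)
    genomes, feats, truth, regions = build_fixture(cfg)
    all_feats = [f for fl in feats.values() for f in fl]
    region_sets = extract_region_sets(list(genomes.values()), all_feats)
    return {
        "config": cfg,
        "genomes": genomes,
        "features": feats,
        "truth": truth,
        "region_sets": region_sets,
    }


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
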