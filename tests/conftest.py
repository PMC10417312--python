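import numpy as np
import pytest

from hicdelta import ContactMap, GenomeModel, demo_config, log2_ratio, simulate_pair


@pytest.fixture(scope="session")
def planted_sim():
    """The default planted fixture: 2 x 200 bins at 100 kb, delta=0.5, seed 7."""
    return simulate_pair(demo_config())


@pytest.fixture(scope="session")
def planted_diff(planted_sim):
    return log2_ratio(planted_sim.treated, planted_sim.control)


@pytest.fixture
def toy_genome():
    """Single 20-bin chromosome, bin size 100 bp."""
    return GenomeModel(("c1",), (2000,), 100)


def make_random_map(genome: GenomeModel, seed: int, density: float = 0.5) -> ContactMap:
    """Random symmetric integer contact map, seeded."""
    rng = np.random.default_rng(seed)
    cis = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        upper = np.triu(rng.poisson(5, size=(n, n)) * (rng.random((n, n)) < density))
        cis[chrom] = upper + np.triu(upper, k=1).T
    return ContactMap(genome, {c: b.astype(float) for c, b in cis.items()})
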