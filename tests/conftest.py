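import numpy as np
import pytest

from breedmix.genotypes import GenotypeMatrix, make_site_table
from breedmix.simulate import SimulationConfig, simulate_reference


def geno(rows, pos=None, chrom="1"):
    """Build a GenotypeMatrix from a samples x sites list of lists."""
    arr = np.asarray(rows, dtype=float)
    n, m = arr.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    sites = make_site_table(np.asarray(pos), chrom=chrom)
    return GenotypeMatrix(arr, [f"s{i + 1}" for i in range(n)], sites)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Four well-differentiated breeds, 10 dogs each, 800 sites."""
    cfg = SimulationConfig(
        n_breeds=4, n_sites=800, samples_per_breed=10, breed_drift=0.25, seed=11
    )
    panel, G, labels = simulate_reference(cfg)
    return cfg, panel, G, labels
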