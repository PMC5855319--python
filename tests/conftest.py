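import numpy as np
import pytest

from gsemkit import GRM, GenotypeMatrix, SimulationDesign, compute_grm, simulate_genotypes


def make_genotypes(rng: np.random.Generator, n: int, m: int,
                   missing_rate: float = 0.0) -> GenotypeMatrix:
    """HWE genotypes with moderate allele frequencies, optional missingness."""
    p = rng.uniform(0.1, 0.5, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    if missing_rate > 0:
        dosages[rng.random((n, m)) < missing_rate] = np.nan
    ids = [(f"F{i}", f"I{i}") for i in range(n)]
    return GenotypeMatrix(dosages=dosages, sample_ids=ids,
                          snp_ids=[f"s{j}" for j in range(m)])


def grm_from_random(rng: np.random.Generator, n: int, m: int) -> GRM:
    """A realistic GRM: estimated from simulated HWE genotypes."""
    return compute_grm(make_genotypes(rng, n, m))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def medium_grm():
    """Shared n=300 GRM with substantial relatedness contrast (m < 2n)."""
    rng = np.random.default_rng(555)
    design = SimulationDesign(n=300, m=400, m_causal=100, n_replicates=1, seed=555)
    return compute_grm(simulate_genotypes(design, seed=555))
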