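import numpy as np
import pytest

from snpca import GenotypeMatrix, RandPCAConfig, SyntheticSpec, simulate_genotypes
from snpca.genotype_io import Variant


def make_genotype_matrix(dosages: np.ndarray) -> GenotypeMatrix:
    """Wrap a raw dosage array with placeholder metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[(f"F{i}", f"I{i}") for i in range(n)],
        variants=[Variant("1", f"snp{j}", j + 1, "A", "B") for j in range(p)],
    )


def spiked_matrix(n: int, p: int, seed: int, decay: float = 0.8, top: float = 10.0):
    """Random matrix with a geometrically decaying singular spectrum.

    Well-separated singular values give unambiguous eigenvectors, which is
    what per-component comparisons between solvers require.
    """
    rng = np.random.default_rng(seed)
    r = min(n, p)
    s = top * decay ** np.arange(r)
    u, _ = np.linalg.qr(rng.standard_normal((n, r)))
    v, _ = np.linalg.qr(rng.standard_normal((p, r)))
    return u @ np.diag(s) @ v.T


@pytest.fixture(scope="session")
def small_structured():
    """3 populations x 40 samples, 800 SNPs — quick but clearly structured."""
    spec = SyntheticSpec(pop_sizes=[40, 40, 40], n_snps=800, fst=0.1, seed=7)
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def study_scale_structured():
    """The full-size simulated study: 3 x 100 samples, 5,000 SNPs, fst 0.1."""
    spec = SyntheticSpec(pop_sizes=[100, 100, 100], n_snps=5000, fst=0.1, seed=1)
    return simulate_genotypes(spec)


@pytest.fixture
def default_cfg():
    return RandPCAConfig(k=10, extra=10, maxiter=10, seed=1)
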