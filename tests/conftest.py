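import numpy as np
import pytest

from genoclust import GenotypeMatrix, from_dosage


@pytest.fixture
def separable_toy() -> tuple[GenotypeMatrix, np.ndarray]:
    """Two groups of 5 diploids at 10 biallelic loci, fixed for alternate
    alleles — trivially separable from any starting point."""
    dosage = np.vstack([np.full((5, 10), 2), np.full((5, 10), 0)])
    return from_dosage(dosage), np.repeat([0, 1], 5)


@pytest.fixture
def hw_toy() -> GenotypeMatrix:
    """Four diploids, one biallelic locus, symmetric counts: genotypes
    (2,0), (1,1), (1,1), (0,2), giving ML frequencies (0.5, 0.5)."""
    counts = np.array([[2, 0], [1, 1], [1, 1], [0, 2]])
    return GenotypeMatrix(
        counts=counts,
        ploidy=2,
        locus_names=["L1"],
        allele_labels=[["1", "2"]],
        individual_ids=[f"i{i}" for i in range(4)],
        missing_mask=np.zeros((4, 1), dtype=bool),
    )


@pytest.fixture
def random_matrix() -> GenotypeMatrix:
    """10 x 20 random diploid biallelic matrix with some missing calls."""
    rng = np.random.default_rng(42)
    dosage = rng.integers(0, 3, size=(10, 20))
    dosage[rng.random(dosage.shape) < 0.1] = -1
    return from_dosage(dosage)
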