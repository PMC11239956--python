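import numpy as np
import pytest

from skyisland import GenotypeMatrix


@pytest.fixture
def two_pop_matrix() -> GenotypeMatrix:
    """Two populations of two individuals with fully homozygous contrast."""
    G = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [2.0, 2.0, 2.0, 2.0],
            [2.0, 2.0, 2.0, 2.0],
        ]
    )
    return GenotypeMatrix(
        genotypes=G,
        individual_ids=["a1", "a2", "b1", "b2"],
        population=["A", "A", "B", "B"],
    )


def random_genotype_matrix(
    rng: np.random.Generator,
    n_pops: int,
    inds_per_pop: int,
    n_loci: int,
    with_groups: bool = False,
    n_groups: int = 2,
) -> GenotypeMatrix:
    """Unstructured random instance for oracle-equivalence checks."""
    n = n_pops * inds_per_pop
    G = rng.integers(0, 3, size=(n, n_loci)).astype(float)
    pops = [f"P{i // inds_per_pop}" for i in range(n)]
    groups = None
    if with_groups:
        pop_to_group = {
            f"P{p}": f"G{p % n_groups}" for p in range(n_pops)
        }
        groups = [pop_to_group[p] for p in pops]
    return GenotypeMatrix(
        genotypes=G,
        individual_ids=[f"i{i}" for i in range(n)],
        population=pops,
        group=groups,
    )
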