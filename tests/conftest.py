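import numpy as np
import pytest

from aneuhic import (
    BinnedContactMap,
    ChromSizes,
    ContactModelParams,
    SyntheticGenomeSpec,
    generate_genome,
)


@pytest.fixture(scope="session")
def toy_chromsizes() -> ChromSizes:
    return ChromSizes.from_dict({"chrA": 500_000, "chrB": 300_000})


def random_contact_map(
    rng: np.random.Generator,
    n_chroms: int = 3,
    max_bins_per_chrom: int = 60,
    resolution: int = 10_000,
    positive: bool = False,
) -> BinnedContactMap:
    """Random symmetric integer contact map over a few toy chromosomes."""
    sizes = {}
    for k in range(n_chroms):
        nb = int(rng.integers(2, max_bins_per_chrom + 1))
        sizes[f"chr{k+1}"] = nb * resolution
    cs = ChromSizes.from_dict(sizes)
    n = sum(v // resolution for v in sizes.values())
    upper = rng.integers(1 if positive else 0, 20, size=(n, n)).astype(float)
    counts = np.triu(upper) + np.triu(upper, 1).T
    return BinnedContactMap(cs, resolution, counts)


@pytest.fixture(scope="session")
def small_genome():
    """Session-wide toy genome used by generator-backed tests."""
    spec = SyntheticGenomeSpec()
    return generate_genome(spec, seed=20)


@pytest.fixture(scope="session")
def default_params() -> ContactModelParams:
    return ContactModelParams(depth=1_000_000)
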