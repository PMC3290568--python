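import numpy as np
import pytest

from standscan.types import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20181108)


@pytest.fixture
def toy_matrix():
    """4 haplotypes x 3 sites with a mix of frequencies."""
    return HaplotypeMatrix(
        np.array(
            [
                [0, 0, 1],
                [0, 1, 1],
                [1, 1, 0],
                [1, 1, 0],
            ],
            dtype=np.int8,
        ),
        positions=[10, 20, 30],
        site_ids=["rs1", "rs2", "rs3"],
        sample_ids=["a", "b", "c", "d"],
    )


def random_matrix(rng, n_hap=20, n_site=30, p=None):
    """Random polymorphic matrix for property tests."""
    if p is None:
        p = rng.uniform(0.1, 0.9, size=n_site)
    hap = (rng.random((n_hap, n_site)) < p).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 100 * n_site), n_site, replace=False))
    return HaplotypeMatrix(hap, positions)
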