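import numpy as np
import pytest

import barcodelim as bl


@pytest.fixture
def toy_alignment() -> bl.Alignment:
    return bl.Alignment.from_pairs(
        [
            ("s1", "AAAA"),
            ("s2", "AATT"),
            ("s3", "TTTT"),
        ]
    )


@pytest.fixture
def toy_tree() -> bl.UltrametricTree:
    return bl.read_newick_string("((a:1,b:1):1,c:2);")


def _balim_incidence() -> bl.CommunityMatrix:
    """Incidence reproducing the four-locality montane-valley community.

    Sites Bokondini/Habbema/Jiwika/Poga with 11/6/13/19 species and pairwise
    shared counts 1 (B-H), 3 (B-J), 2 (B-P), 3 (H-J), 4 (H-P), 6 (J-P);
    three species span three localities to realize the overlap structure.
    """
    occ: list[tuple[str, str]] = []

    def add(species: str, sites: list[str]) -> None:
        occ.extend((species, s) for s in sites)

    B, H, J, P = "Bokondini", "Habbema", "Jiwika", "Poga"
    add("h1", [H, B])
    add("h2", [H, J, P])
    add("h3", [H, J, P])
    add("h4", [H, P])
    add("h5", [H, J, P])
    add("h6", [H])
    for i in range(3):
        add(f"x{i}", [B, J])
    for i in range(2):
        add(f"y{i}", [B, P])
    for i in range(3):
        add(f"z{i}", [J, P])
    for i in range(5):
        add(f"b{i}", [B])
    for i in range(4):
        add(f"j{i}", [J])
    for i in range(10):
        add(f"p{i}", [P])
    cm = bl.CommunityMatrix.from_occurrences(occ)
    return bl.CommunityMatrix(cm.incidence[[B, H, J, P]])


@pytest.fixture
def balim_incidence() -> bl.CommunityMatrix:
    return _balim_incidence()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_distance_matrix(
    rng: np.random.Generator, n: int = 40
) -> bl.DistanceMatrix:
    """Random symmetric distance matrix (not metric; clustering only needs
    symmetry)."""
    d = rng.uniform(0.0, 0.25, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = tuple(f"q{i:03d}" for i in range(n))
    n_sites = np.full((n, n), 658, dtype=int)
    return bl.DistanceMatrix(ids, d, n_sites)
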