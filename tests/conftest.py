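import pytest

from treelens import parse_newick, random_binary_tree


@pytest.fixture
def four_leaf_pair():
    """Same-topology 4-leaf trees, internal lengths 0.3 and 0.5."""
    a = parse_newick("((A:1,B:1):0.3,C:1,D:1);", name="a")
    b = parse_newick("((A:1,B:1):0.5,C:1,D:1);", name="b")
    return a, b


@pytest.fixture
def sqrt2_pair():
    """5-leaf pair whose geodesic has a 2-leg support and length sqrt(2).

    T holds splits {1,2} (0.1) and {4,5} (0.9); T' holds {2,3} (0.9)
    and {1,5} (0.1); the cone path would give ~1.81108.
    """
    T = parse_newick("((L1:1,L2:1):0.1,L3:1,(L4:1,L5:1):0.9);", name="T")
    Tp = parse_newick("((L2:1,L3:1):0.9,L4:1,(L1:1,L5:1):0.1);", name="Tp")
    return T, Tp


def random_pair(n_leaves, seed):
    """Two independent random binary trees on a shared leaf set."""
    t1 = random_binary_tree(n_leaves, seed=seed, name=f"r{seed}a")
    t2 = random_binary_tree(n_leaves, seed=seed + 10_000, name=f"r{seed}b")
    return t1, t2
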