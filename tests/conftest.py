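import numpy as np
import pytest

from plastoscan import Alignment, parse_newick
from plastoscan.substmodel import GTRGIParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gtr_params():
    """A deliberately asymmetric GTR+G+I parameter set."""
    return GTRGIParams(
        exchangeabilities=(1.3, 2.5, 0.7, 1.1, 3.3, 1.0),
        freqs=(0.3, 0.2, 0.2, 0.3),
        alpha=0.5,
        p_inv=0.3,
        n_cat=4,
    )


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.1,B:0.3):0.15,(C:0.2,D:0.05):0.4);")


def random_gtr_params(rng, p_inv_max=0.5):
    ex = tuple(rng.uniform(0.2, 4.0, size=5)) + (1.0,)
    f = rng.dirichlet([10, 10, 10, 10])
    f = f / f.sum()
    return GTRGIParams(
        exchangeabilities=ex,
        freqs=tuple(f),
        alpha=float(rng.uniform(0.2, 2.0)),
        p_inv=float(rng.uniform(0.0, p_inv_max)),
        n_cat=int(rng.integers(1, 5)),
    )


def random_tree_newick(rng, n_leaves, min_bl=0.01, max_bl=0.5):
    """Random binary topology by sequential leaf attachment."""
    labels = [f"t{i}" for i in range(n_leaves)]

    def bl():
        return rng.uniform(min_bl, max_bl)

    subtrees = [f"{lab}:{bl():.4f}" for lab in labels]
    rng.shuffle(subtrees)
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{bl():.4f}")
    return "(" + ",".join(subtrees) + ");"


@pytest.fixture
def toy_alignment():
    return Alignment.from_sequences(
        ["t1", "t2", "t3"],
        ["ACGT", "A-GT", "AC-T"],
    )
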