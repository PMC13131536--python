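import numpy as np
import pytest

from ddpcm import parse_newick


@pytest.fixture(scope="session")
def two_taxon_tree():
    """Two tips with root-to-tip paths 1.0 and 0.7 whose ancestor sits at
    height 0.4 above the root (BM covariances 0.80/0.56/0.32 at sigma2=0.8)."""
    return parse_newick("((T1:0.6,T2:0.3):0.4);")


@pytest.fixture(scope="session")
def three_taxon_tree():
    return parse_newick("((A:0.6,B:0.3):0.4,C:1.0);")


@pytest.fixture(scope="session")
def cherry_half_shared():
    """Ultrametric 2-taxon tree whose shared fraction of total depth is 0.5."""
    return parse_newick("((A:0.5,B:0.5):0.5);")


@pytest.fixture(scope="session")
def four_taxon_tree():
    return parse_newick("(((A:0.5,B:0.5):0.3,C:0.8):0.2,D:1.0);")


def pair_logdensity_surface(tree, grid, sigma2, x0):
    """Joint log-density of the two tip values on every bin pair.

    Root prior is a point mass at the bin containing x0; returns an (n, n)
    array of log f(x_1, x_2) evaluated at bin-center pairs.
    """
    from ddpcm.likelihood import Propagator
    from ddpcm.discretize import generator_diffusion

    prop = Propagator(generator_diffusion(grid, sigma2))
    # walk: root -> internal -> two tips (2-taxon tree with a root stem)
    internal = [i for i in range(tree.n_nodes)
                if i != tree.root and tree.labels[i] is None]
    assert len(internal) == 1
    v = prop.matrix(tree.edge_length[internal[0]])[grid.bin_of(x0)]
    t1, t2 = (tree.edge_length[i] for i in tree.tip_ids)
    P1 = prop.matrix(t1)
    P2 = prop.matrix(t2)
    pij = np.einsum("s,si,sj->ij", v, P1, P2)
    with np.errstate(divide="ignore"):
        return np.log(pij) - 2.0 * np.log(grid.delta)
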