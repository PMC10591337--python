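import numpy as np
import pytest

import xasgnn as x


@pytest.fixture(scope="session")
def grid():
    return x.make_grid(270.0, 300.0, 100)


@pytest.fixture(scope="session")
def dataset(grid):
    """Small synthetic dataset shared across tests (fixed seed)."""
    return x.generate_dataset(60, seed=11, grid=grid)


@pytest.fixture(scope="session")
def ethanol_graph():
    return x.build_graph("CCO")


def random_graph(rng: np.random.Generator) -> x.MolecularGraph:
    """A random connected heavy-atom graph with valid feature encodings."""
    from xasgnn.molgraph import (EDGE_FEATURE_DIM, ELEMENTS, HYBRIDIZATIONS,
                                 featurize_atom)
    n = int(rng.integers(2, 9))
    elements = [ELEMENTS[rng.integers(len(ELEMENTS))] for _ in range(n)]
    feats = np.stack([
        featurize_atom(el, HYBRIDIZATIONS[rng.integers(4)],
                       bool(rng.integers(2)), int(rng.integers(4)))
        for el in elements])
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]  # random tree
    extra = int(rng.integers(0, 2))
    for _ in range(extra):
        v, w = sorted(rng.choice(n, size=2, replace=False).tolist())
        if (v, w) not in edges:
            edges.append((v, w))
    efeats = np.zeros((len(edges), EDGE_FEATURE_DIM))
    for i in range(len(edges)):
        efeats[i, rng.integers(4)] = 1.0
    return x.MolecularGraph(
        molecule_id="random", elements=elements, node_features=feats,
        edges=edges, edge_features=efeats,
        hydrogen_counts=[int(f[-1]) for f in feats])
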