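import numpy as np
import pytest

from wmconn.connectome import BinaryGraph
from wmconn.masking import BinaryMask
from wmconn.synthetic import SyntheticVolumeSpec, make_tissue_maps


@pytest.fixture(scope="session")
def volume_spec() -> SyntheticVolumeSpec:
    return SyntheticVolumeSpec(seed=7)


@pytest.fixture(scope="session")
def wm_blob(volume_spec):
    wm, gm, csf = make_tissue_maps(volume_spec)
    return wm


@pytest.fixture(scope="session")
def blob_mask(wm_blob, volume_spec):
    return BinaryMask(wm_blob > 0.9, volume_spec.affine)


def random_graph(rng: np.random.Generator, n: int, p: float) -> BinaryGraph:
    """An Erdos-Renyi binary graph with at least one edge."""
    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, k=1)
        adj = adj | adj.T
        if adj.any():
            return BinaryGraph(adj)


@pytest.fixture(scope="session")
def random_graphs():
    """30 small random graphs spanning sparse to dense regimes."""
    rng = np.random.default_rng(1234)
    graphs = []
    for i in range(30):
        n = int(rng.integers(5, 13))
        p = float(rng.uniform(0.2, 0.9))
        graphs.append(random_graph(rng, n, p))
    return graphs
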