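import networkx as nx
import numpy as np
import pandas as pd
import pytest

import soilnet as sn


def make_otu(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"OTU{j + 1}" for j in range(counts.shape[1])]
    return sn.OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))


def make_net(edges, nodes=None, group=None):
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return sn.CoNetwork(g, group=group)


@pytest.fixture
def toy_otu():
    return make_otu([[10, 0, 5, 1], [3, 7, 0, 2], [8, 2, 4, 6]])


@pytest.fixture
def triangle():
    return make_net([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def two_triangles():
    return make_net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture(scope="session")
def default_cohort():
    """The paper-like fixture: 3 groups x 10 samples."""
    return sn.simulate_counts(sn.SimSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for pipeline-level tests."""
    spec = sn.SimSpec(
        groups=[sn.GroupSpec("forest", 6, 80, 1.0, depth_mean=3000),
                sn.GroupSpec("arable", 6, 120, 1.0, depth_mean=3000),
                sn.GroupSpec("wetland", 6, 100, 1.0, depth_mean=3000)],
        blocks=[sn.BlockSpec(6, 0.9), sn.BlockSpec(6, 0.9)],
        env_effects=[sn.EnvEffectSpec("pH", 6, 1.0)],
        seed=11,
    )
    return sn.simulate_counts(spec)


def random_graph(rng, n_max=50, p=None):
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.05, 0.6)) if p is None else p
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
    return sn.CoNetwork(g)
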