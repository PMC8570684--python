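import numpy as np
import pytest

from fosnet import (
    RegionAtlas,
    load_packaged_atlas,
    synthetic_atlas,
)
from fosnet.cartography import WeightedGraph
from fosnet.clustering import ModulePartition

import networkx as nx


@pytest.fixture(scope="session")
def packaged_atlas() -> RegionAtlas:
    return load_packaged_atlas()


@pytest.fixture
def small_atlas() -> RegionAtlas:
    return synthetic_atlas(4, prefix="N")


def build_graph(atlas, edges, threshold=0.01):
    """Weighted graph on `atlas` from (i, j, w) index triples."""
    g = nx.Graph()
    ab = atlas.abbreviations
    g.add_nodes_from(ab)
    g.add_weighted_edges_from((ab[i], ab[j], w) for i, j, w in edges)
    return WeightedGraph(graph=g, atlas=atlas, threshold=threshold)


def build_partition(atlas, labels):
    return ModulePartition(labels=np.asarray(labels), atlas=atlas)
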