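"""Weighted node cartography of the thresholded correlation graph.

The functional graph keeps only strong positive edges: an undirected edge
(i, j) with weight r_ij is included iff r_ij >= rmin (0.75 by default,
inclusive).  On that graph, with modules s_i from hierarchical clustering,
two classic node-role statistics of Guimera & Amaral are computed in their
weighted form, where every degree is a *summed edge weight*:

within-module degree z-score
    WMDz_i = (k_i^within - mean_{j in s_i} k_j^within) / sd_{j in s_i} k_j^within,
    with k_i^within the summed weight of edges from i to other members of
    its own module, and the population (divide-by-n) standard deviation.
    Measures intramodular importance.

participation coefficient
    P_i = 1 - sum_s (k_is / k_i)^2, with k_is the summed weight of edges
    from i into module s and k_i the total summed weight.  0 when all of a
    node's weight stays in one module, approaching 1 when spread evenly
    across modules.  Measures intermodular reach.

Degenerate cases take the neutral role value 0: WMDz in a singleton or
uniform-degree module (sd = 0), PC of an isolated node (k_i = 0).

Hubs: a region is flagged high-PC at PC >= 0.30 and high-WMDz at
WMDz >= 0.80 (both inclusive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .clustering import ModulePartition
from .connectivity import CorrelationMatrix

__all__ = [
    "WeightedGraph",
    "NodeMetricsTable",
    "NetworkSummary",
    "threshold_graph",
    "within_module_degree_z",
    "participation_coefficient",
    "compute_node_metrics",
    "classify_hubs",
    "summarize_network",
    "export_graph",
    "load_exported_graph",
    "write_metrics",
    "DEFAULT_EDGE_THRESHOLD",
    "DEFAULT_PC_MIN",
    "DEFAULT_WMDZ_MIN",
]

DEFAULT_EDGE_THRESHOLD = 0.75
DEFAULT_PC_MIN = 0.30
DEFAULT_WMDZ_MIN = 0.80


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph on the full region frame; edges carry correlation weights.

    All atlas regions are present as nodes even when isolated, so a region
    disconnected at the chosen threshold stays in every table.
    """

    graph: nx.Graph
    atlas: RegionAtlas = field(repr=False)
    threshold: float = DEFAULT_EDGE_THRESHOLD

    def __post_init__(self) -> None:
        g = self.graph
        if set(g.nodes) != set(self.atlas.abbreviations):
            raise ValueError("graph nodes must be exactly the atlas regions")
        for u, v, w in g.edges(data="weight"):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if w is None or w < self.threshold:
                raise ValueError("all edge weights must be >= the threshold")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight_matrix(self) -> np.ndarray:
        order = list(self.atlas.abbreviations)
        return nx.to_numpy_array(self.graph, nodelist=order, weight="weight")


@dataclass(frozen=True)
class NodeMetricsTable:
    """Per-region module assignment, role metrics, and hub flags."""

    frame: pd.DataFrame  # columns: region, abbreviation, module, degree,
    # within_degree, pc, wmdz, high_pc, high_wmdz
    pc_min: float = DEFAULT_PC_MIN
    wmdz_min: float = DEFAULT_WMDZ_MIN

    def __post_init__(self) -> None:
        required = {"region", "abbreviation", "module", "pc", "wmdz", "high_pc", "high_wmdz"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"metrics table missing column(s): {sorted(missing)}")


@dataclass(frozen=True)
class NetworkSummary:
    """Edge count, module structure, and hub census of one network."""

    group_label: str
    n_edges: int
    n_modules: int
    module_sizes: dict[int, int]
    n_high_pc_only: int
    n_high_wmdz_only: int
    n_both: int

    def to_dict(self) -> dict:
        return {
            "group": self.group_label,
            "n_edges": self.n_edges,
            "n_modules": self.n_modules,
            "module_sizes": {str(k): v for k, v in sorted(self.module_sizes.items())},
            "n_high_pc_only": self.n_high_pc_only,
            "n_high_wmdz_only": self.n_high_wmdz_only,
            "n_both": self.n_both,
        }

    def write(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)
            f.write("\n")


def threshold_graph(c: CorrelationMatrix, rmin: float = DEFAULT_EDGE_THRESHOLD) -> WeightedGraph:
    """Keep edges with correlation >= rmin (inclusive); positive weights only."""
    if not 0.0 < rmin <= 1.0:
        raise ValueError("edge threshold must lie in (0, 1]")
    ab = c.atlas.abbreviations
    g = nx.Graph()
    g.add_nodes_from(ab)
    v = c.values
    ii, jj = np.nonzero(np.triu(v >= rmin, k=1))
    g.add_weighted_edges_from((ab[i], ab[j], float(v[i, j])) for i, j in zip(ii, jj))
    return WeightedGraph(graph=g, atlas=c.atlas, threshold=float(rmin))


def _degree_by_module(g: WeightedGraph, p: ModulePartition) -> tuple[np.ndarray, np.ndarray]:
    """Return (k_is matrix of shape (n_regions, n_modules), module labels)."""
    labels = p.labels
    w = g.weight_matrix()
    n_mod = p.n_modules
    k_is = np.zeros((len(labels), n_mod))
    for s in range(1, n_mod + 1):
        k_is[:, s - 1] = w[:, labels == s].sum(axis=1)
    return k_is, labels


def _check_coverage(g: WeightedGraph, p: ModulePartition) -> None:
    if g.atlas.abbreviations != p.atlas.abbreviations:
        raise ValueError("graph and partition are built on different atlases")


def within_module_degree_z(g: WeightedGraph, p: ModulePartition) -> np.ndarray:
    """Weighted within-module degree z-score per region (atlas order)."""
    _check_coverage(g, p)
    k_is, labels = _degree_by_module(g, p)
    k_within = k_is[np.arange(len(labels)), labels - 1]
    wmdz = np.zeros(len(labels))
    for s in np.unique(labels):
        members = labels == s
        ks = k_within[members]
        sd = ks.std()  # population sd over the module's regions
        # a uniform-degree module has sd 0 up to roundoff in the mean;
        # compare against the degree scale so z stays at the neutral 0
        tol = 1e-12 * max(1.0, float(np.abs(ks).max(initial=0.0)))
        if members.sum() > 1 and sd > tol:
            wmdz[members] = (ks - ks.mean()) / sd
    return wmdz


def participation_coefficient(g: WeightedGraph, p: ModulePartition) -> np.ndarray:
    """Weighted participation coefficient per region (atlas order)."""
    _check_coverage(g, p)
    k_is, _ = _degree_by_module(g, p)
    k_i = k_is.sum(axis=1)
    pc = np.zeros(len(k_i))
    connected = k_i > 0
    frac = k_is[connected] / k_i[connected, None]
    pc[connected] = 1.0 - np.sum(frac * frac, axis=1)
    return np.clip(pc, 0.0, 1.0)


def compute_node_metrics(
    g: WeightedGraph,
    p: ModulePartition,
    pc_min: float = DEFAULT_PC_MIN,
    wmdz_min: float = DEFAULT_WMDZ_MIN,
) -> NodeMetricsTable:
    """Full per-region cartography table with hub flags."""
    _check_coverage(g, p)
    k_is, labels = _degree_by_module(g, p)
    frame = pd.DataFrame(
        {
            "region": list(g.atlas.names),
            "abbreviation": list(g.atlas.abbreviations),
            "module": labels,
            "degree": k_is.sum(axis=1),
            "within_degree": k_is[np.arange(len(labels)), labels - 1],
            "pc": participation_coefficient(g, p),
            "wmdz": within_module_degree_z(g, p),
        }
    )
    table = NodeMetricsTable(
        frame=frame.assign(high_pc=False, high_wmdz=False), pc_min=pc_min, wmdz_min=wmdz_min
    )
    return classify_hubs(table, pc_min=pc_min, wmdz_min=wmdz_min)


def classify_hubs(
    metrics: NodeMetricsTable,
    pc_min: float = DEFAULT_PC_MIN,
    wmdz_min: float = DEFAULT_WMDZ_MIN,
) -> NodeMetricsTable:
    """Flag high-PC and high-WMDz regions; both thresholds are inclusive."""
    frame = metrics.frame.copy()
    frame["high_pc"] = frame["pc"] >= pc_min
    frame["high_wmdz"] = frame["wmdz"] >= wmdz_min
    return NodeMetricsTable(frame=frame, pc_min=pc_min, wmdz_min=wmdz_min)


def summarize_network(
    g: WeightedGraph, metrics: NodeMetricsTable, p: ModulePartition, group_label: str = ""
) -> NetworkSummary:
    """Edge count, module sizes, and the disjoint hub census."""
    hp = metrics.frame["high_pc"].to_numpy()
    hw = metrics.frame["high_wmdz"].to_numpy()
    return NetworkSummary(
        group_label=group_label or "network",
        n_edges=g.n_edges,
        n_modules=p.n_modules,
        module_sizes=p.module_sizes(),
        n_high_pc_only=int(np.sum(hp & ~hw)),
        n_high_wmdz_only=int(np.sum(hw & ~hp)),
        n_both=int(np.sum(hp & hw)),
    )


def export_graph(g: WeightedGraph, metrics: NodeMetricsTable, path) -> None:
    """Write GraphML (or GEXF for a .gexf path) with node attributes.

    Node attributes: region name, module, pc, wmdz, hub flags.  Isolated
    nodes are preserved.  Round-trips losslessly via
    :func:`load_exported_graph`.
    """
    out = nx.Graph()
    rows = metrics.frame.set_index("abbreviation")
    for ab in g.atlas.abbreviations:
        row = rows.loc[ab]
        out.add_node(
            ab,
            region=str(row["region"]),
            module=int(row["module"]),
            pc=float(row["pc"]),
            wmdz=float(row["wmdz"]),
            high_pc=bool(row["high_pc"]),
            high_wmdz=bool(row["high_wmdz"]),
        )
    out.add_weighted_edges_from(
        (u, v, float(w)) for u, v, w in g.graph.edges(data="weight")
    )
    if str(path).endswith(".gexf"):
        nx.write_gexf(out, path)
    else:
        nx.write_graphml(out, path)


def load_exported_graph(path) -> nx.Graph:
    if str(path).endswith(".gexf"):
        return nx.read_gexf(path)
    return nx.read_graphml(path)


def write_metrics(metrics: NodeMetricsTable, path) -> None:
    """Node metrics CSV mirroring the published per-network tables."""
    frame = metrics.frame.copy()
    frame["high_pc"] = frame["high_pc"].astype(int)
    frame["high_wmdz"] = frame["high_wmdz"].astype(int)
    frame.to_csv(path, index=False, float_format="%.12g")
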