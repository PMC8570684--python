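"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_oracle(x: np.ndarray) -> np.ndarray:
    """Textbook Pearson r between columns of x: cov / (sd_i * sd_j)."""
    n, p = x.shape
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = x[:, i], x[:, j]
            am, bm = a - a.mean(), b - b.mean()
            denom = math.sqrt((am * am).sum() * (bm * bm).sum())
            rij = (am * bm).sum() / denom
            r[i, j] = r[j, i] = rij
    return r


def complete_linkage_cophenetic(d: np.ndarray) -> np.ndarray:
    """Cophenetic matrix of complete linkage, by exhaustive agglomeration.

    At each step every cluster pair's complete (max) distance is recomputed
    from the original matrix and the minimum is merged; ties break on the
    lexicographically smallest member indices.
    """
    n = d.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                key = (dist, tuple(sorted(clusters[a] | clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _), a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = dist
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph


def node_metrics_oracle(
    edges: list[tuple[int, int, float]], labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(PC, WMDz) per node via explicit double loops over the edge list.

    labels: 1-based module id per node.  Conventions: PC = 0 for k_i = 0;
    WMDz = 0 when the module's within-degree sd (population) is 0 or the
    module is a singleton.
    """
    n = len(labels)
    modules = sorted(set(int(m) for m in labels))
    k_total = np.zeros(n)
    k_to_mod = {(i, s): 0.0 for i in range(n) for s in modules}
    for u, v, w in edges:
        k_total[u] += w
        k_total[v] += w
        k_to_mod[(u, int(labels[v]))] += w
        k_to_mod[(v, int(labels[u]))] += w

    pc = np.zeros(n)
    for i in range(n):
        if k_total[i] > 0:
            pc[i] = 1.0 - sum((k_to_mod[(i, s)] / k_total[i]) ** 2 for s in modules)

    k_within = np.array([k_to_mod[(i, int(labels[i]))] for i in range(n)])
    wmdz = np.zeros(n)
    for s in modules:
        members = [i for i in range(n) if labels[i] == s]
        vals = k_within[members]
        mean = vals.mean()
        sd = math.sqrt(((vals - mean) ** 2).mean())
        tol = 1e-12 * max(1.0, float(np.abs(vals).max())) if len(vals) else 0.0
        if len(members) > 1 and sd > tol:
            for i in members:
                wmdz[i] = (k_within[i] - mean) / sd
    return pc, wmdz


def random_weighted_graph(
    rng: np.random.Generator, max_nodes: int = 20
) -> tuple[int, list[tuple[int, int, float]], np.ndarray]:
    """A random weighted graph with a random 1-based partition."""
    n = int(rng.integers(4, max_nodes + 1))
    n_mod = int(rng.integers(1, min(n, 6) + 1))
    labels = rng.integers(1, n_mod + 1, size=n)
    # relabel contiguously in order of first appearance
    seen: dict[int, int] = {}
    labels = np.array([seen.setdefault(int(l), len(seen) + 1) for l in labels])
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((i, j, float(rng.uniform(0.05, 1.0))))
    return n, edges, labels
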