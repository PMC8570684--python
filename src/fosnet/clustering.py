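"""Module detection by complete-linkage hierarchical clustering.

Regions are clustered on their connectivity profiles: the distance between
two regions is the Euclidean norm of the difference of their full rows of
the correlation matrix (all region coordinates, self-correlations
included).  Complete linkage merges the pair of clusters whose farthest
members are closest, which yields monotone (non-decreasing) merge heights.
Modules are the flat clusters obtained by cutting the dendrogram at a
fraction of its total height — half the tree height by default — and a
sweep over cut fractions probes how robust the module count is to that
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .atlas import RegionAtlas
from .connectivity import CorrelationMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ModulePartition",
    "correlation_profile_distances",
    "complete_linkage",
    "cut_tree_at_fraction",
    "module_count_sweep",
    "write_partition",
    "write_sweep",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative region x region distances with zero diagonal."""

    values: np.ndarray
    atlas: RegionAtlas = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distances must be nonnegative with a zero diagonal")
        object.__setattr__(self, "values", (v + v.T) / 2.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form.

    ``merges`` is the (n-1, 4) linkage matrix: each row is
    (left cluster id, right cluster id, merge height, resulting size),
    with original observations numbered 0..n-1 and new clusters n, n+1, ...
    """

    merges: np.ndarray
    atlas: RegionAtlas = field(repr=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.merges, dtype=float)
        if z.shape != (len(self.atlas) - 1, 4) and len(self.atlas) > 1:
            raise ValueError("linkage matrix must have n-1 merges")
        heights = z[:, 2] if z.size else np.empty(0)
        if heights.size and np.any(np.diff(heights) < -1e-10):
            raise ValueError("complete-linkage merge heights must be non-decreasing")
        object.__setattr__(self, "merges", z)

    @property
    def max_height(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights; a merge-order-invariant tree summary."""
        return squareform(cophenet(self.merges))


@dataclass(frozen=True)
class ModulePartition:
    """Region -> module assignment from a dendrogram cut.

    Module ids are contiguous 1..n_modules, numbered by each module's
    smallest region index in atlas order.
    """

    labels: np.ndarray  # (n_regions,) ints in 1..n_modules
    atlas: RegionAtlas = field(repr=False)
    cut_fraction: float = float("nan")
    cut_height: float = float("nan")

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.shape != (len(self.atlas),):
            raise ValueError("one module label per atlas region required")
        uniq = np.unique(lab)
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("module ids must be contiguous 1..n_modules")
        object.__setattr__(self, "labels", lab)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    def module_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"abbreviation": list(self.atlas.abbreviations), "module": self.labels}
        )


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (smallest index)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        out[i] = mapping[r]
    return out


def correlation_profile_distances(c: CorrelationMatrix) -> DistanceMatrix:
    """Euclidean distance between full correlation rows.

    d(i, j) = || row_i - row_j || over all region coordinates, the i-th and
    j-th (self-correlation) coordinates included.
    """
    v = c.values
    sq = np.sum(v * v, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
    d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, atlas=c.atlas)


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Complete-method agglomerative clustering of a distance matrix."""
    condensed = squareform(d.values, checks=False)
    z = linkage(condensed, method="complete")
    return Dendrogram(merges=z, atlas=d.atlas)


def cut_tree_at_fraction(t: Dendrogram, fraction: float) -> ModulePartition:
    """Cut the tree at ``fraction`` x (max merge height).

    All merges with height <= the cut height are applied, so fraction 1.0
    always yields a single module and fraction 0.0 separates all distinct
    regions (only exact duplicates, merged at height 0, stay together).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("cut fraction must lie in [0, 1]")
    if len(t.atlas) == 1:
        return ModulePartition(
            labels=np.array([1]), atlas=t.atlas, cut_fraction=fraction, cut_height=0.0
        )
    cut_height = fraction * t.max_height
    raw = fcluster(t.merges, t=cut_height, criterion="distance")
    return ModulePartition(
        labels=_canonical_labels(np.asarray(raw)),
        atlas=t.atlas,
        cut_fraction=float(fraction),
        cut_height=float(cut_height),
    )


def module_count_sweep(
    t: Dendrogram, fractions: "list[float] | np.ndarray"
) -> list[tuple[float, int]]:
    """Module count at each cut fraction (robustness sweep)."""
    return [(float(f), cut_tree_at_fraction(t, float(f)).n_modules) for f in fractions]


def write_partition(p: ModulePartition, path) -> None:
    p.to_frame().to_csv(path, index=False)


def write_sweep(sweep: list[tuple[float, int]], path) -> None:
    pd.DataFrame(sweep, columns=["fraction", "n_modules"]).to_csv(
        path, index=False, float_format="%.12g"
    )
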