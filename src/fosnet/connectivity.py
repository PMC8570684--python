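"""Group-level functional connectivity: interregional Pearson correlation.

Functional connectivity between two regions is the sample Pearson
correlation of their log10 Fos activity across the animals of one treatment
group.  Each group is correlated separately; no pooling across groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import LogActivityMatrix, RegionAtlas

__all__ = ["CorrelationMatrix", "ConstantRegionWarning", "pearson_connectivity",
           "write_correlation", "load_correlation"]


class ConstantRegionWarning(UserWarning):
    """A region was constant across animals; its correlations are undefined."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric region x region Pearson r with unit diagonal."""

    values: np.ndarray
    atlas: RegionAtlas = field(repr=False)
    group_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if v.shape[0] != len(self.atlas):
            raise ValueError("correlation matrix does not match atlas size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ab = list(self.atlas.abbreviations)
        return pd.DataFrame(self.values, index=ab, columns=ab)


def pearson_connectivity(x: LogActivityMatrix) -> CorrelationMatrix:
    """Pearson correlation of every region pair across animals.

    Requires at least 3 animals (2 points give a degenerate +/-1); a
    warning is emitted for 3-5 animals, where single-animal noise still
    moves individual coefficients substantially.  Regions constant across
    animals have undefined correlations; those entries are recorded as 0
    and the regions are named in a :class:`ConstantRegionWarning`, keeping
    the full region frame intact (a zero-variance region can never form a
    thresholded edge).
    """
    v = x.values
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 animals to estimate correlations")
    if n <= 5:
        warnings.warn(
            f"only {n} animals: correlation estimates are noisy", UserWarning, stacklevel=2
        )
    sd = v.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v, rowvar=False)
    if constant.size:
        names = [x.atlas.abbreviations[i] for i in constant]
        warnings.warn(
            f"region(s) constant across animals, correlations set to 0: {names}",
            ConstantRegionWarning,
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, atlas=x.atlas, group_label=x.group_label)


def write_correlation(c: CorrelationMatrix, path) -> None:
    """CSV with abbreviation row/column headers, 12 significant digits."""
    c.to_frame().to_csv(path, float_format="%.12g", index_label="abbreviation")


def load_correlation(path, atlas: RegionAtlas, group_label: str = "") -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0)
    df = df.loc[list(atlas.abbreviations), list(atlas.abbreviations)]
    return CorrelationMatrix(values=df.to_numpy(), atlas=atlas, group_label=group_label)
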