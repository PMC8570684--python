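"""Region atlas and Fos count-table I/O.

The analysis frame is a fixed, ordered catalog of brain regions (name,
abbreviation, anatomical group).  Every downstream matrix — counts, log
activity, correlation — is indexed by this atlas, with the abbreviation as
the canonical region identifier.  A 178-region mouse-brain catalog covering
cortical plate through cerebellum ships with the package
(:func:`load_packaged_atlas`).

Counts of Fos-positive nuclei span orders of magnitude across regions
(tens to thousands), so they are brought onto a comparable scale with a
log10 transform before any connectivity computation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionAtlas",
    "FosCountMatrix",
    "LogActivityMatrix",
    "AtlasFormatError",
    "AtlasValidationError",
    "CountValidationError",
    "load_region_atlas",
    "load_packaged_atlas",
    "load_fos_counts",
    "write_fos_counts",
    "log10_normalize",
]


class AtlasFormatError(ValueError):
    """Atlas file is structurally malformed (missing columns, empty)."""


class AtlasValidationError(ValueError):
    """Atlas content violates an invariant (duplicate names/abbreviations)."""


class CountValidationError(ValueError):
    """Count table content is invalid against the atlas or count domain."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered catalog of brain regions.

    Row order is significant: it defines the canonical region index shared
    by every matrix in the pipeline.
    """

    names: tuple[str, ...]
    abbreviations: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise AtlasValidationError("atlas is empty")
        if not (len(self.names) == len(self.abbreviations) == len(self.groups)):
            raise AtlasValidationError("atlas columns have unequal lengths")
        for label, values in (("name", self.names), ("abbreviation", self.abbreviations)):
            seen: set[str] = set()
            for v in values:
                if v in seen:
                    raise AtlasValidationError(f"duplicate region {label}: {v!r}")
                seen.add(v)

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, abbreviation: str) -> int:
        return self.abbreviations.index(abbreviation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "abbreviation": self.abbreviations, "group": self.groups}
        )


@dataclass(frozen=True)
class FosCountMatrix:
    """Animals x regions table of Fos-positive nucleus counts for one group."""

    group_label: str
    animal_ids: tuple[str, ...]
    counts: np.ndarray  # (n_animals, n_regions) nonnegative integers
    atlas: RegionAtlas = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountValidationError("counts must be a 2-D animals x regions array")
        if counts.shape[0] != len(self.animal_ids):
            raise CountValidationError("number of animal ids does not match count rows")
        if counts.shape[1] != len(self.atlas):
            raise CountValidationError(
                f"count columns ({counts.shape[1]}) do not match atlas size ({len(self.atlas)})"
            )
        if counts.shape[0] < 2:
            raise CountValidationError("need at least 2 animals per group")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise CountValidationError("counts must be integers; fractional values rejected")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise CountValidationError("counts must be nonnegative")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.atlas.abbreviations))
        df.insert(0, "animal_id", list(self.animal_ids))
        return df


@dataclass(frozen=True)
class LogActivityMatrix:
    """log10(count + pseudocount) activity, same frame as the count matrix."""

    group_label: str
    animal_ids: tuple[str, ...]
    values: np.ndarray  # (n_animals, n_regions) float
    atlas: RegionAtlas = field(repr=False)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("log activity must be finite everywhere")
        object.__setattr__(self, "values", values)

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]


def load_region_atlas(path) -> RegionAtlas:
    """Read a region atlas from CSV with header ``name,abbreviation,group``.

    File row order is preserved and becomes the canonical region order.
    Duplicate names or abbreviations are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"name", "abbreviation", "group"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasFormatError(f"atlas file missing column(s): {sorted(missing)}")
    if df[list(required)].isna().any().any():
        raise AtlasFormatError("atlas file contains empty cells")
    return RegionAtlas(
        names=tuple(df["name"]),
        abbreviations=tuple(df["abbreviation"]),
        groups=tuple(df["group"]),
    )


def load_packaged_atlas() -> RegionAtlas:
    """The packaged 178-region mouse-brain atlas."""
    ref = importlib.resources.files("fosnet.data") / "atlas.csv"
    with importlib.resources.as_file(ref) as path:
        return load_region_atlas(path)


def load_fos_counts(path, atlas: RegionAtlas, group_label: str) -> FosCountMatrix:
    """Read a per-group count CSV (``animal_id`` then region abbreviations).

    Columns may appear in any order; they are canonicalized to atlas order.
    Unknown or missing region columns and negative/fractional counts are
    rejected with the offending entries named.
    """
    df = pd.read_csv(path)
    if "animal_id" not in df.columns:
        raise CountValidationError("count file must have an 'animal_id' column")
    region_cols = [c for c in df.columns if c != "animal_id"]
    unknown = sorted(set(region_cols) - set(atlas.abbreviations))
    if unknown:
        raise CountValidationError(f"unknown region column(s) not in atlas: {unknown}")
    absent = sorted(set(atlas.abbreviations) - set(region_cols))
    if absent:
        raise CountValidationError(f"count file missing atlas region(s): {absent}")
    data = df[list(atlas.abbreviations)]
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CountValidationError("non-numeric count values present")
    return FosCountMatrix(
        group_label=group_label,
        animal_ids=tuple(str(a) for a in df["animal_id"]),
        counts=values,
        atlas=atlas,
    )


def write_fos_counts(m: FosCountMatrix, path) -> None:
    """Write a count matrix as CSV; exact round-trip with :func:`load_fos_counts`."""
    m.to_frame().to_csv(path, index=False)


def log10_normalize(m: FosCountMatrix, pseudocount: float = 1.0) -> LogActivityMatrix:
    """Elementwise ``log10(count + pseudocount)``.

    A pseudocount of 1 keeps zero counts at 0 on the log scale and is
    negligible against counts in the thousands.  Zero counts with a zero
    pseudocount are a domain error (log10(0) undefined).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0 and np.any(m.counts == 0):
        raise ValueError("zero counts present; a positive pseudocount is required")
    values = np.log10(m.counts.astype(float) + float(pseudocount))
    return LogActivityMatrix(
        group_label=m.group_label,
        animal_ids=m.animal_ids,
        values=values,
        atlas=m.atlas,
        pseudocount=float(pseudocount),
    )
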