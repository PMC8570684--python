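"""Synthetic Fos-count groups with planted modular correlation structure.

Real per-animal regional Fos counts span tens to thousands and, within a
treatment group, co-fluctuate across animals in blocks of regions.  The
generator emulates exactly that on the log10 scale with a single latent
factor per module:

    x_{r,a} = mu_r + loading * f_{m(r),a} + eps_{r,a}
    f_{m,a} ~ N(0, 1),  eps_{r,a} ~ N(0, noise_sd^2),  mu_r ~ U(mean_log_range)
    count_{r,a} = round(10 ** x_{r,a}), clipped at 0

Regions sharing a module share the factor, so their population Pearson
correlation on the log scale is loading^2 / (loading^2 + noise_sd^2);
regions in different modules are uncorrelated.  The planted module map is
returned alongside the counts, giving every downstream stage a ground
truth to recover.

Per-group random streams are derived from a master seed plus a stable hash
of the group label, so adding or removing a group never perturbs the data
of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .atlas import FosCountMatrix, RegionAtlas

__all__ = ["SyntheticConfig", "PlantedTruth", "generate_group_counts", "generate_study",
           "synthetic_atlas", "study_scenario"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-module count generator.

    loading is the shared-factor weight (lambda) and noise_sd the residual
    sigma, both on the log10 scale; mean_log_range bounds the per-region
    baselines mu_r, whose default (1.0, 3.5) spans counts of ~10 to ~3000.
    """

    n_modules: int
    regions_per_module: tuple[int, ...]
    n_animals: int
    loading: float = 2.0
    noise_sd: float = 0.5
    mean_log_range: tuple[float, float] = (1.0, 3.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or len(self.regions_per_module) != self.n_modules:
            raise ValueError("regions_per_module must list one size per module")
        if any(s < 1 for s in self.regions_per_module):
            raise ValueError("module sizes must be positive")
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if self.loading < 0:
            raise ValueError("loading must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.mean_log_range
        if lo > hi:
            raise ValueError("mean_log_range must satisfy low <= high")
        object.__setattr__(self, "regions_per_module", tuple(self.regions_per_module))

    @property
    def n_regions(self) -> int:
        return sum(self.regions_per_module)


@dataclass(frozen=True)
class PlantedTruth:
    """True region -> module labels (1..n_modules, atlas order)."""

    labels: np.ndarray
    atlas: RegionAtlas = field(repr=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.shape != (len(self.atlas),):
            raise ValueError("one true label per region required")
        object.__setattr__(self, "labels", lab)


def synthetic_atlas(n_regions: int, prefix: str = "R") -> RegionAtlas:
    """A minimal atlas of n_regions placeholder regions for simulations."""
    return RegionAtlas(
        names=tuple(f"Synthetic region {i + 1:03d}" for i in range(n_regions)),
        abbreviations=tuple(f"{prefix}{i + 1:03d}" for i in range(n_regions)),
        groups=tuple("Synthetic" for _ in range(n_regions)),
    )


def _group_rng(master_seed: int, group_label: str | None) -> np.random.Generator:
    if group_label is None:
        return np.random.default_rng(master_seed)
    return np.random.default_rng([master_seed, zlib.crc32(group_label.encode("utf-8"))])


def generate_group_counts(
    cfg: SyntheticConfig,
    group_label: str = "synthetic",
    atlas: RegionAtlas | None = None,
    _rng: np.random.Generator | None = None,
) -> tuple[FosCountMatrix, PlantedTruth]:
    """Draw one group's count table under the planted-module model.

    Deterministic given (cfg.seed, group_label).  If an atlas is supplied
    its size must equal the configured region total; otherwise a synthetic
    atlas is created.
    """
    if atlas is None:
        atlas = synthetic_atlas(cfg.n_regions)
    elif len(atlas) != cfg.n_regions:
        raise ValueError("atlas size does not match configured region total")
    rng = _rng if _rng is not None else np.random.default_rng(cfg.seed)

    labels = np.repeat(np.arange(1, cfg.n_modules + 1), cfg.regions_per_module)
    lo, hi = cfg.mean_log_range
    mu = rng.uniform(lo, hi, size=cfg.n_regions)
    factors = rng.standard_normal((cfg.n_modules, cfg.n_animals))
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_animals, cfg.n_regions))
    log_activity = mu[None, :] + cfg.loading * factors[labels - 1, :].T + eps
    counts = np.maximum(np.rint(10.0 ** log_activity), 0.0).astype(np.int64)

    matrix = FosCountMatrix(
        group_label=group_label,
        animal_ids=tuple(f"{group_label}_{a + 1:02d}" for a in range(cfg.n_animals)),
        counts=counts,
        atlas=atlas,
    )
    return matrix, PlantedTruth(labels=labels, atlas=atlas)


def generate_study(
    cfgs: dict[str, SyntheticConfig], master_seed: int | None = None
) -> dict[str, tuple[FosCountMatrix, PlantedTruth]]:
    """Generate several independent treatment groups.

    Each group's stream comes from (master seed, crc32(group label));
    master_seed defaults to each config's own seed.  Group labels must be
    unique (dict input enforces this; an explicit check guards against
    accidental label collisions after normalization).
    """
    if not cfgs:
        raise ValueError("at least one group is required")
    labels = [str(k) for k in cfgs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    out: dict[str, tuple[FosCountMatrix, PlantedTruth]] = {}
    for label, cfg in cfgs.items():
        seed = cfg.seed if master_seed is None else master_seed
        rng = _group_rng(seed, str(label))
        out[str(label)] = generate_group_counts(cfg, group_label=str(label), _rng=rng)
    return out


def study_scenario(
    n_animals: int = 5,
    n_regions: int = 178,
    module_counts: dict[str, int] | None = None,
    loading: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict[str, SyntheticConfig]:
    """Configs emulating a four-group study: control plus three drug groups
    with progressively fewer, larger modules (7/4/3/5 by default)."""
    if module_counts is None:
        module_counts = {"saline": 7, "cocaine": 4, "methamphetamine": 3, "nicotine": 5}
    cfgs = {}
    for label, k in module_counts.items():
        base, extra = divmod(n_regions, k)
        sizes = tuple(base + (1 if i < extra else 0) for i in range(k))
        cfgs[label] = SyntheticConfig(
            n_modules=k,
            regions_per_module=sizes,
            n_animals=n_animals,
            loading=loading,
            noise_sd=noise_sd,
            seed=seed,
        )
    return cfgs
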