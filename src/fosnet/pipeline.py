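"""End-to-end per-group analysis and the cross-group comparison table.

One group runs: log10-normalize counts -> Pearson correlation -> profile
distances -> complete-linkage dendrogram -> half-height module partition
(+ cut-fraction sweep) -> thresholded weighted graph -> node cartography
(PC, WMDz, hub flags) -> network summary -> GraphML export.  Groups are
fully independent computations; the comparison table at the end is purely
descriptive (edge counts, module counts, hub censuses per group).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import (
    FosCountMatrix,
    LogActivityMatrix,
    load_fos_counts,
    load_region_atlas,
    log10_normalize,
)
from .cartography import (
    DEFAULT_EDGE_THRESHOLD,
    DEFAULT_PC_MIN,
    DEFAULT_WMDZ_MIN,
    NetworkSummary,
    NodeMetricsTable,
    compute_node_metrics,
    export_graph,
    summarize_network,
    threshold_graph,
    write_metrics,
)
from .clustering import (
    ModulePartition,
    complete_linkage,
    correlation_profile_distances,
    cut_tree_at_fraction,
    module_count_sweep,
    write_partition,
    write_sweep,
)
from .connectivity import CorrelationMatrix, pearson_connectivity, write_correlation

__all__ = ["PipelineConfig", "GroupResult", "run_group", "run_study"]

log = logging.getLogger("fosnet")

DEFAULT_SWEEP = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters; the defaults are the study's stated values
    (half-height cut, 0.75 edge threshold, PC >= 0.30, WMDz >= 0.80)."""

    atlas_path: str | None = None
    group_count_paths: dict[str, str] = field(default_factory=dict)
    pseudocount: float = 1.0
    cut_fraction: float = 0.5
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    pc_min: float = DEFAULT_PC_MIN
    wmdz_min: float = DEFAULT_WMDZ_MIN
    sweep_fractions: tuple[float, ...] = DEFAULT_SWEEP
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut_fraction <= 1.0:
            raise ValueError("cut_fraction must lie in [0, 1]")
        if not 0.0 < self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must lie in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if any(not 0.0 <= f <= 1.0 for f in self.sweep_fractions):
            raise ValueError("sweep fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "atlas_path": self.atlas_path,
            "group_count_paths": dict(self.group_count_paths),
            "pseudocount": self.pseudocount,
            "cut_fraction": self.cut_fraction,
            "edge_threshold": self.edge_threshold,
            "pc_min": self.pc_min,
            "wmdz_min": self.wmdz_min,
            "sweep_fractions": list(self.sweep_fractions),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class GroupResult:
    """All artifacts of one group's analysis."""

    group_label: str
    log_activity: LogActivityMatrix
    correlation: CorrelationMatrix
    partition: ModulePartition
    metrics: NodeMetricsTable
    summary: NetworkSummary
    sweep: list[tuple[float, int]]


def _stage(name: str):
    """Attach the pipeline stage name to any error it raises."""

    class _ctx:
        def __enter__(self):
            log.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def run_group(counts: FosCountMatrix, cfg: PipelineConfig, out_dir=None) -> GroupResult:
    """Run the full analysis for one treatment group.

    If ``out_dir`` is given, writes correlation.csv, partition.csv,
    metrics.csv, summary.json, sweep.csv and network.graphml there.
    Deterministic: identical inputs and config yield byte-identical files.
    """
    label = counts.group_label
    with _stage(f"{label}:normalize"):
        x = log10_normalize(counts, pseudocount=cfg.pseudocount)
    with _stage(f"{label}:correlate"):
        c = pearson_connectivity(x)
    with _stage(f"{label}:cluster"):
        tree = complete_linkage(correlation_profile_distances(c))
        partition = cut_tree_at_fraction(tree, cfg.cut_fraction)
        sweep = module_count_sweep(tree, list(cfg.sweep_fractions))
    with _stage(f"{label}:cartography"):
        graph = threshold_graph(c, rmin=cfg.edge_threshold)
        metrics = compute_node_metrics(
            graph, partition, pc_min=cfg.pc_min, wmdz_min=cfg.wmdz_min
        )
        summary = summarize_network(graph, metrics, partition, group_label=label)
    if out_dir is not None:
        with _stage(f"{label}:write"):
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_correlation(c, out / "correlation.csv")
            write_partition(partition, out / "partition.csv")
            write_metrics(metrics, out / "metrics.csv")
            summary.write(out / "summary.json")
            write_sweep(sweep, out / "sweep.csv")
            export_graph(graph, metrics, out / "network.graphml")
    return GroupResult(
        group_label=label,
        log_activity=x,
        correlation=c,
        partition=partition,
        metrics=metrics,
        summary=summary,
        sweep=sweep,
    )


def comparison_table(results: dict[str, GroupResult]) -> pd.DataFrame:
    """One descriptive row per group: edges, modules, hub census."""
    rows = []
    for label, res in results.items():
        s = res.summary
        rows.append(
            {
                "group": label,
                "n_animals": res.log_activity.n_animals,
                "n_edges": s.n_edges,
                "n_modules": s.n_modules,
                "largest_module_size": max(s.module_sizes.values()),
                "n_high_pc_only": s.n_high_pc_only,
                "n_high_wmdz_only": s.n_high_wmdz_only,
                "n_both": s.n_both,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    cfg: PipelineConfig, counts_by_group: dict[str, FosCountMatrix] | None = None
) -> tuple[dict[str, GroupResult], pd.DataFrame]:
    """Run every group independently and build the comparison table.

    Count tables are either passed in directly or loaded from
    ``cfg.group_count_paths`` against ``cfg.atlas_path``.  All input files
    are checked before any computation starts.  If ``cfg.output_dir`` is
    set, per-group artifacts go to ``<output_dir>/<group>/`` plus a
    top-level comparison.csv and a run manifest.
    """
    if counts_by_group is None:
        if cfg.atlas_path is None or not cfg.group_count_paths:
            raise ValueError("config must provide atlas_path and group_count_paths")
        missing = [p for p in [cfg.atlas_path, *cfg.group_count_paths.values()]
                   if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        atlas = load_region_atlas(cfg.atlas_path)
        counts_by_group = {
            label: load_fos_counts(path, atlas, label)
            for label, path in cfg.group_count_paths.items()
        }
    if not counts_by_group:
        raise ValueError("at least one group is required")

    out_root = Path(cfg.output_dir) if cfg.output_dir else None
    results: dict[str, GroupResult] = {}
    for label, counts in counts_by_group.items():
        out_dir = out_root / label if out_root else None
        results[label] = run_group(counts, cfg, out_dir=out_dir)

    table = comparison_table(results)
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_root / "comparison.csv", index=False)
        _write_manifest(cfg, counts_by_group, out_root)
    return results, table


def _write_manifest(cfg, counts_by_group, out_root: Path) -> None:
    digests = {
        label: hashlib.sha256(m.counts.tobytes()).hexdigest()[:16]
        for label, m in counts_by_group.items()
    }
    manifest = {
        "fosnet_version": __version__,
        "config": cfg.to_dict(),
        "input_digests": digests,
    }
    with open(out_root / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
        f.write("\n")
    log.info("wrote manifest to %s", out_root / "run_manifest.json")
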