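"""Published per-network node-metric tables, packaged for regression checks.

Four reference tables ship with the package, one per treatment network
(saline control, cocaine, methamphetamine, nicotine withdrawal).  Each
lists every brain region's module assignment, participation coefficient,
and within-module degree z-score as printed to two decimals.  The nicotine
table has 177 rows: the interanterodorsal thalamic nucleus was
disconnected from that network and carries no role metrics.

These tables are *outputs* of the original analysis — the raw per-animal
counts behind them are not available — so they serve as fixed regression
fixtures for summaries and hub classification, not as pipeline inputs.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .cartography import DEFAULT_PC_MIN, DEFAULT_WMDZ_MIN

__all__ = ["REFERENCE_GROUPS", "load_reference_metrics", "reference_hub_census"]

REFERENCE_GROUPS = ("saline", "cocaine", "methamphetamine", "nicotine")


def load_reference_metrics(group: str) -> pd.DataFrame:
    """Reference node table for one network.

    Columns: region, abbreviation, module, pc, wmdz.
    """
    if group not in REFERENCE_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {REFERENCE_GROUPS}")
    ref = importlib.resources.files("fosnet.data") / f"{group}_metrics.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_hub_census(
    group: str, pc_min: float = DEFAULT_PC_MIN, wmdz_min: float = DEFAULT_WMDZ_MIN
) -> dict[str, int]:
    """Hub counts (high PC only / high WMDz only / both) for a reference table."""
    df = load_reference_metrics(group)
    hp = df["pc"] >= pc_min
    hw = df["wmdz"] >= wmdz_min
    return {
        "n_high_pc_only": int((hp & ~hw).sum()),
        "n_high_wmdz_only": int((hw & ~hp).sum()),
        "n_both": int((hp & hw).sum()),
    }
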