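"""Diversity statistics over a scaffold hierarchy.

Three views of how a compound library spreads over the tree: branching
factor bins per level, percentile distributions of children-per-scaffold,
and top-k most frequent scaffolds with cumulative coverage.  These are the
analytic tools used to judge whether a hierarchy level is displayable —
the bin edges come from square screen grids (100 cells in a 10x10 grid,
400 in 20x20, 1600 in 40x40).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy

#: Branching bins: optimal, good, large, excessive.
BIN_EDGES = (100, 400, 1600)
BIN_LABELS = ("1-100", "101-400", "401-1600", ">1600")

PERCENTILE_POINTS = (0, 10, 25, 50, 75, 90, 95, 99, 100)


def _child_counts(h: Hierarchy, level: int) -> list[int]:
    return [n.child_count for n in h.level_nodes(level)]


def branching_bins(h: Hierarchy) -> pd.DataFrame:
    """Scaffolds per level binned by number of children.

    Levels 0-7 only (level-8 nodes are leaves here); scaffolds with zero
    children cannot occur in a hierarchy built from full chains, and are
    excluded if present in a hand-edited file.  Percentages are relative
    to the number of binned scaffolds at the level.
    """
    rows = []
    for level in range(8):
        counts = [c for c in _child_counts(h, level) if c >= 1]
        total = len(counts)
        row: dict[str, object] = {"level": level, "scaffolds": total}
        for lo, hi, label in zip((1,) + tuple(e + 1 for e in BIN_EDGES),
                                 BIN_EDGES + (math.inf,), BIN_LABELS):
            k = sum(1 for c in counts if lo <= c <= hi)
            row[label] = k
            row[f"{label} %"] = round(100.0 * k / total, 2) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


def nearest_rank_percentile(values: list[int], p: float) -> int:
    """Nearest-rank percentile: always an observed value, no interpolation."""
    if not values:
        raise ValueError("percentile of empty multiset")
    ordered = sorted(values)
    if p <= 0:
        return ordered[0]
    rank = math.ceil(p / 100.0 * len(ordered))
    return ordered[min(rank, len(ordered)) - 1]


def children_percentiles(h: Hierarchy) -> pd.DataFrame:
    """Distribution of children-per-scaffold for each level 0-7.

    Nearest-rank percentiles (P0=min .. P100=max) plus the arithmetic
    mean.  A level with a single node (always level 0) has every statistic
    equal to that node's child count.  Empty levels are reported absent.
    """
    rows = []
    for level in range(8):
        counts = _child_counts(h, level)
        if not counts:
            continue
        row: dict[str, object] = {"level": level}
        for p in PERCENTILE_POINTS:
            row[f"P{p}"] = nearest_rank_percentile(counts, p)
        row["mean"] = round(float(np.mean(counts)), 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


def top_scaffolds(h: Hierarchy, level: int, k: int = 10) -> pd.DataFrame:
    """The k most frequent scaffolds at a level, with coverage.

    Sorted by background frequency descending, ties broken by key string;
    percentages are relative to the hierarchy's molecule count and the
    cumulative column gives the fraction of the library covered by the
    top ranks so far.  ``k`` larger than the level returns the full level.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = sorted(h.level_nodes(level),
                   key=lambda n: (-n.background_freq, n.key.key))
    total = h.molecule_count
    rows = []
    cum = 0
    for rank, node in enumerate(nodes[:k], start=1):
        cum += node.background_freq
        rows.append({
            "rank": rank,
            "key": node.key.key,
            "frequency": node.background_freq,
            "frequency_pct": round(100.0 * node.background_freq / total, 2)
            if total else 0.0,
            "children": node.child_count,
            "coverage_pct": round(100.0 * cum / total, 2) if total else 0.0,
        })
    return pd.DataFrame(rows)


def format_table(df: pd.DataFrame) -> str:
    """Aligned-text rendering for terminal output."""
    return df.to_string()
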