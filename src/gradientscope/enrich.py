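"""Over-representation analysis of selected genes against GMT gene sets.

Standard one-sided hypergeometric enrichment of a thresholded gene list
(e.g. VIP > 1) against a scored-gene universe, with Benjamini-Hochberg FDR
across the retained sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .groupstats import bh_fdr

__all__ = ["hypergeom_enrich"]

logger = logging.getLogger(__name__)


def hypergeom_enrich(
    selected: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric tail enrichment of ``selected`` within each gene set.

    For each set, ``p = P(overlap >= k)`` given universe size N, set size K
    (after intersecting with the universe) and selection size n; q is BH-FDR
    across all retained sets.  Sets that do not intersect the universe are
    dropped with a log entry.  Results are sorted by q, then p.
    """
    universe_set = set(universe)
    if len(universe_set) < 2:
        raise ValueError("universe must contain at least 2 genes")
    selected_set = set(selected)
    if not selected_set:
        raise ValueError("selected gene list is empty")
    stray = selected_set - universe_set
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")

    n_universe = len(universe_set)
    n_selected = len(selected_set)
    rows = []
    for name, members in sets.items():
        in_universe = set(members) & universe_set
        if not in_universe:
            logger.info("gene set %r does not intersect the universe; dropped", name)
            continue
        k = len(in_universe & selected_set)
        big_k = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_selected))
        rows.append(
            {"set": name, "k": k, "K": big_k, "n": n_selected, "N": n_universe, "p": min(p, 1.0)}
        )
    if not rows:
        raise ValueError("no gene set intersects the universe")
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
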