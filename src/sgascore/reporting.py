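"""Cross-query summaries: call-set overlaps and fitness-change distributions."""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def overlap_counts(call_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-partition counts of up to three call sets.

    Returns one row per non-empty membership signature (e.g. strains called
    in queries A and B but not C) with its exact strain count, plus one
    ``total`` row per query.  Region counts sum to the size of the union.
    With more than 3 queries a pairwise-intersection table is returned
    instead (and a note is logged).
    """
    queries = list(call_sets)
    if not 1 <= len(queries):
        raise ValueError("need at least one call set")
    if len(queries) > 3:
        logger.info("%d queries: emitting pairwise overlap table", len(queries))
        return _pairwise_table(call_sets)

    universe = set().union(*call_sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for strain in universe:
        members = tuple(q for q in queries if strain in call_sets[q])
        regions[members] = regions.get(members, 0) + 1
    rows = []
    for k in range(1, len(queries) + 1):
        for combo in combinations(queries, k):
            if combo in regions:
                rows.append(("+".join(combo), "region", regions[combo]))
    for q in queries:
        rows.append((q, "total", len(call_sets[q])))
    return pd.DataFrame(rows, columns=["queries", "kind", "count"])


def _pairwise_table(call_sets: dict[str, set[str]]) -> pd.DataFrame:
    rows = []
    for a, b in combinations(call_sets, 2):
        rows.append((f"{a}+{b}", "pairwise", len(call_sets[a] & call_sets[b])))
    for q, s in call_sets.items():
        rows.append((q, "total", len(s)))
    return pd.DataFrame(rows, columns=["queries", "kind", "count"])


def fitness_distribution_summary(
    records: pd.DataFrame,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-query quantiles of the normalized colony-size change (Wij).

    ``records`` needs columns ``query``, ``wij`` and ``usable``; only usable
    records enter the quantiles.
    """
    rows = []
    for query, sub in records.groupby("query", sort=True):
        w = sub.loc[sub["usable"].astype(bool), "wij"].dropna().to_numpy()
        if len(w) == 0:
            continue
        qs = np.quantile(w, quantiles)
        rows.append([query, len(w), *qs])
    cols = ["query", "n"] + [f"q{int(q * 100):02d}" for q in quantiles]
    return pd.DataFrame(rows, columns=cols)


def call_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-query counts of each interaction class."""
    tab = (
        records.groupby(["query", "interaction_class"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    return tab.reset_index()
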