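"""End-to-end screen scoring: normalize -> filter -> W/S -> test -> classify.

``score_screen`` is the one-call interface used by the CLI and the
simulation studies; each stage is also available separately from its own
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import INDUCED, UNINDUCED, ArrayLayout, PlateGrid
from .gridprep import (
    FilterConfig,
    collect_observations,
    low_area_drops,
    normalize_plate,
)
from .scoring import WTriple, compute_w_triples, fd_score, s_score
from .difftest import (
    CLASS_FILTERED,
    TestConfig,
    classify,
    replicate_differentials,
    test_query,
)

RESULT_COLUMNS = [
    "strain", "query", "wij", "wi", "wj", "s_score", "fd",
    "log2_differential", "moderated_stat", "p_value", "q_value",
    "control_wij", "interaction_class", "usable", "filter_flags",
]


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    test: TestConfig = field(default_factory=TestConfig)
    normalize: bool = True
    spatial_window: int = 9
    plate_normalize_to: float | None = None  # off by default, see gridprep
    fd_defect_positive: bool = True


def score_screen(
    pairs: list[tuple[PlateGrid, ArrayLayout]],
    control_query: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Score a full multi-query screen and return one record per strain x query.

    ``pairs`` are (plate, layout) pairs covering the induced and uninduced
    plates of every query, the control query included.  Strains failing the
    low-area filter in any screen are excluded from all screens (class
    ``filtered``); q-values are BH-adjusted within each query.
    """
    cfg = config or PipelineConfig()
    if cfg.normalize:
        pairs = [
            (normalize_plate(p, window=cfg.spatial_window,
                             plate_normalize_to=cfg.plate_normalize_to), lay)
            for p, lay in pairs
        ]
    else:
        pairs = [(p.copy_with(p.area), lay) for p, lay in pairs]

    observations = collect_observations(pairs, cfg.filters)
    dropped = low_area_drops(observations, cfg.filters.low_area_min_sum)
    kept = [o for o in observations if o.strain_id not in dropped]

    queries = sorted({o.query_id for o in observations})
    if control_query not in queries:
        raise KeyError(f"control query {control_query!r} not among plates")

    triples: dict[str, dict[str, WTriple]] = {
        q: (compute_w_triples(kept, q) if kept else {}) for q in queries
    }
    control_wij = {
        strain: w.wij for strain, w in triples[control_query].items() if w.usable
    }

    frames = []
    for q in queries:
        diffs = replicate_differentials(kept, q)
        tests = test_query(diffs, cfg.test).set_index("strain")
        strains = sorted(triples[q])
        rec = pd.DataFrame({"strain": strains})
        rec["query"] = q
        rec["wij"] = [triples[q][s].wij for s in strains]
        rec["wi"] = [triples[q][s].wi for s in strains]
        rec["wj"] = [triples[q][s].wj for s in strains]
        rec["s_score"] = [s_score(triples[q][s]) for s in strains]
        rec["fd"] = [
            fd_score(triples[q][s], defect_positive=cfg.fd_defect_positive)
            for s in strains
        ]
        for col in ("log2_differential", "moderated_stat", "p_value", "q_value"):
            rec[col] = [
                tests.at[s, col] if s in tests.index else np.nan for s in strains
            ]
        rec["control_wij"] = [control_wij.get(s, np.nan) for s in strains]
        rec["usable"] = [
            triples[q][s].usable and np.isfinite(rec["q_value"].iloc[i])
            for i, s in enumerate(strains)
        ]
        rec["interaction_class"] = classify(
            rec["s_score"], rec["q_value"], rec["control_wij"], rec["usable"],
            cfg.test,
        )
        rec["filter_flags"] = ""
        frames.append(rec)

    records = pd.concat(frames, ignore_index=True)

    if dropped:
        drop_rows = []
        for q in queries:
            for s in sorted(dropped):
                drop_rows.append({
                    "strain": s, "query": q, "wij": np.nan, "wi": np.nan,
                    "wj": np.nan, "s_score": np.nan, "fd": np.nan,
                    "log2_differential": np.nan, "moderated_stat": np.nan,
                    "p_value": np.nan, "q_value": np.nan, "control_wij": np.nan,
                    "interaction_class": CLASS_FILTERED, "usable": False,
                    "filter_flags": "low_area",
                })
        records = pd.concat([records, pd.DataFrame(drop_rows)], ignore_index=True)
    return records[RESULT_COLUMNS].sort_values(["query", "strain"]).reset_index(drop=True)
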