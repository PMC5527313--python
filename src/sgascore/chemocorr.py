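"""Correlation of fitness-defect profiles with a reference chemogenomic matrix.

A screen's per-strain FD profile is compared against every experiment of a
reference strains x experiments FD matrix by pairwise-complete Pearson
correlation; p-values come from the exact t-transform
t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom, are
BH-adjusted across the reported experiments, and experiments with
q <= 0.01 (default) are called significant.  Experiments sharing fewer
than ``min_overlap`` strains with the profile, or with zero variance in
either vector, are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import ReferenceFDMatrix
from .scoring import FDProfile
from .difftest import bh_adjust


@dataclass
class CorrelationResult:
    experiment_id: str
    signature_label: str
    r: float
    n_overlap: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def correlate_fd_profiles(
    profile: FDProfile,
    ref: ReferenceFDMatrix,
    min_overlap: int = 30,
    corr_q_max: float = 0.01,
) -> list[CorrelationResult]:
    """Pearson-correlate one FD profile against every reference experiment."""
    fd = profile.fd.dropna()
    results: list[CorrelationResult] = []
    for exp in ref.scores.columns:
        col = ref.scores[exp]
        shared = fd.index.intersection(col.dropna().index)
        if len(shared) < min_overlap:
            continue
        x = fd.loc[shared].to_numpy(dtype=float)
        y = col.loc[shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        results.append(
            CorrelationResult(
                experiment_id=str(exp),
                signature_label=str(ref.signatures[exp]),
                r=float(r),
                n_overlap=len(shared),
                p_value=float(p),
            )
        )
    if results:
        q = bh_adjust([res.p_value for res in results])
        for res, qv in zip(results, q):
            res.q_value = float(qv)
            res.significant = bool(qv <= corr_q_max)
    return results


def signature_summary(results: list[CorrelationResult], top_k: int = 10) -> pd.DataFrame:
    """Rank signatures by their best significant correlation.

    Per signature label: number of significant experiments, the maximum r
    and the mean r among them; ranked by max r descending, ties broken by
    count then label order.
    """
    sig = [res for res in results if res.significant]
    if not sig:
        return pd.DataFrame(
            columns=["signature", "n_significant", "max_r", "mean_r"]
        )
    df = pd.DataFrame(
        {
            "signature": [res.signature_label for res in sig],
            "r": [res.r for res in sig],
        }
    )
    agg = (
        df.groupby("signature", sort=True)["r"]
        .agg(n_significant="size", max_r="max", mean_r="mean")
        .reset_index()
    )
    agg = agg.sort_values(
        by=["max_r", "n_significant", "signature"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return agg.head(top_k)


def results_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "experiment": [r.experiment_id for r in results],
            "signature": [r.signature_label for r in results],
            "r": [r.r for r in results],
            "n": [r.n_overlap for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
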