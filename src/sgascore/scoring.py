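"""Median-ratio W statistics and the multiplicative interaction score.

For an induction screen with query q and arrayed mutant x:

* ``Wij`` — observed induction effect on mutant x: median area of x's
  colonies on the induced plate over the median on the uninduced plate of
  the same query.
* ``Wi``  — expected (screen-wide) induction effect for query q: median of
  *all* colonies on the induced plates over the median of all on the
  uninduced plates of q.
* ``Wj``  — mutant x's baseline fitness effect: median of x's colonies on
  the uninduced plates of *all* queries over the median of all colonies on
  those plates.

The multiplicative interaction score is S = Wij - Wi*Wj: zero under
independence, positive = alleviating, negative = aggravating/synthetic sick.
All medians are taken over retained (unflagged, non-missing) replicates;
every statistic is a ratio, so the scores are invariant to a global
rescaling of colony areas.

The compound mode handles screens where a second perturbation (a petite
[rho-] background, or hydroxyurea) replaces the arrayed mutation: there
Wij is the induction response *within* the variant — a conditional ratio —
so independence corresponds to Wij = Wj and the score is computed as the
conditional contrast S = Wij - Wj (Wi, the variant's baseline effect, is
reported alongside).  Strongly negative scores (< -0.1) are called
synthetic sick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import INDUCED, UNINDUCED
from .gridprep import ReplicateObservation

MODE_INDUCTION = "induction"
MODE_COMPOUND = "compound"


@dataclass
class WTriple:
    wij: float
    wi: float
    wj: float
    mode: str = MODE_INDUCTION
    usable: bool = True

    def __post_init__(self) -> None:
        if self.usable and not all(
            np.isfinite(v) for v in (self.wij, self.wi, self.wj)
        ):
            self.usable = False


@dataclass
class FDProfile:
    """Per-strain fitness-defect scores (log2 scale) for one screen."""

    query_id: str
    fd: pd.Series  # index strain, finite for usable strains only


def compute_w_triples(
    observations: list[ReplicateObservation],
    query: str,
) -> dict[str, WTriple]:
    """W triples for every strain of one query.

    ``observations`` must cover the induced and uninduced plates of the
    query *and* the uninduced plates of every other query (needed for Wj).
    Strains absent from some queries' uninduced plates fall back to the
    queries where they were measured.
    """
    queries = sorted({o.query_id for o in observations})
    if query not in queries:
        raise KeyError(f"query {query!r} not present in observations")

    per_strain: dict[tuple[str, str, str], np.ndarray] = {}
    for o in observations:
        per_strain[(o.strain_id, o.query_id, o.condition)] = o.retained

    def pooled(query_id: str, condition: str) -> np.ndarray:
        chunks = [
            v for (s, q, c), v in per_strain.items()
            if q == query_id and c == condition and len(v)
        ]
        return np.concatenate(chunks) if chunks else np.array([])

    wi = _ratio(_median(pooled(query, INDUCED)), _median(pooled(query, UNINDUCED)))

    # Wj denominator: all colonies on the uninduced plates of all queries
    unind_all = np.concatenate(
        [pooled(q, UNINDUCED) for q in queries]
    ) if queries else np.array([])
    wj_denom = _median(unind_all)

    strains = sorted({o.strain_id for o in observations if o.query_id == query})
    out: dict[str, WTriple] = {}
    for strain in strains:
        ind = per_strain.get((strain, query, INDUCED), np.array([]))
        unind = per_strain.get((strain, query, UNINDUCED), np.array([]))
        wij = _ratio(_median(ind), _median(unind))
        strain_unind = [
            per_strain.get((strain, q, UNINDUCED), np.array([])) for q in queries
        ]
        strain_unind = [v for v in strain_unind if len(v)]
        wj_num = _median(np.concatenate(strain_unind)) if strain_unind else float("nan")
        wj = _ratio(wj_num, wj_denom)
        out[strain] = WTriple(wij=wij, wi=wi, wj=wj)
    return out


def s_score(w: WTriple) -> float:
    """Multiplicative interaction score.

    Induction mode: S = Wij - Wi*Wj.  Compound mode: S = Wij - Wj (see
    module docstring for why the conditional contrast is used).
    """
    if not w.usable:
        return float("nan")
    if w.mode == MODE_COMPOUND:
        return w.wij - w.wj
    return w.wij - w.wi * w.wj


def compound_w_triple(
    parent_untreated: float,
    parent_treated: float,
    variant_untreated: float,
    variant_treated: float,
) -> WTriple:
    """W triple for a petite/hydroxyurea-style compound screen.

    Wi = variant baseline effect (variant_untreated / parent_untreated);
    Wj = induction response of the parent (parent_treated / parent_untreated);
    Wij = induction response within the variant
    (variant_treated / variant_untreated).
    """
    usable = parent_untreated > 0 and variant_untreated > 0
    if not usable:
        return WTriple(float("nan"), float("nan"), float("nan"),
                       mode=MODE_COMPOUND, usable=False)
    return WTriple(
        wij=variant_treated / variant_untreated,
        wi=variant_untreated / parent_untreated,
        wj=parent_treated / parent_untreated,
        mode=MODE_COMPOUND,
    )


def is_synthetic_sick(w: WTriple, sick_max: float = -0.1) -> bool:
    """Compound-mode synthetic-sick call: S below the sick threshold."""
    s = s_score(w)
    return bool(np.isfinite(s) and s < sick_max)


def fd_score(w: WTriple, *, defect_positive: bool = True) -> float:
    """Fitness-defect score from the observed induction effect.

    FD = -log2(Wij) by default, so a colony-size drop on induction gives a
    positive defect score; ``defect_positive=False`` flips the sign for
    matching references with the opposite convention.
    """
    if not w.usable or w.wij <= 0:
        return float("nan")
    val = -np.log2(w.wij)
    return float(val if defect_positive else -val)


def fd_profile(triples: dict[str, WTriple], query: str,
               *, defect_positive: bool = True) -> FDProfile:
    fd = pd.Series(
        {s: fd_score(w, defect_positive=defect_positive) for s, w in triples.items()}
    ).dropna()
    return FDProfile(query_id=query, fd=fd)


def _median(values: np.ndarray) -> float:
    return float(np.median(values)) if len(values) else float("nan")


def _ratio(num: float, denom: float) -> float:
    if not np.isfinite(num) or not np.isfinite(denom) or denom == 0:
        return float("nan")
    return num / denom
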