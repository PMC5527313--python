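"""Moderated fold-threshold testing of induction responses.

Each strain's induction response is the mean of its paired per-slot log2
differentials d_r = log2(induced_r) - log2(uninduced_r).  The null
hypothesis is not "no change" but "the same change as the screen at large":
effects are centered on the median strain differential, and significance
requires the centered effect to exceed a fold threshold (default 1.3-fold,
i.e. tau = log2(1.3) on the log scale), a threshold test in the style of
limma's treat.

Per-strain variances are moderated with an empirical-Bayes scaled
inverse-chi-square prior fitted by matching the first two moments of the
log sample variances; the posterior variance
s2_post = (d0*s0^2 + df*s2) / (d0 + df) pools each strain's variance toward
the prior with d0 prior degrees of freedom.  The composite-tail p-value

    p = P(T_df >= (|delta| - tau)/se) + P(T_df >= (|delta| + tau)/se)

with df = n_pairs - 1 + d0 reduces to the two-sided moderated t-test at
tau = 0, and to the unmoderated test at d0 = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .plate_io import INDUCED
from .gridprep import ReplicateObservation

logger = logging.getLogger(__name__)

CLASS_POSITIVE = "positive"
CLASS_NEGATIVE = "negative"
CLASS_NONE = "none"
CLASS_FILTERED = "filtered"


@dataclass
class TestConfig:
    """Thresholds for calling interactions.

    Defaults: 1.3-fold analysis threshold, q <= 0.05, |S| > 0.3 with sign
    giving the direction, a control-query window [0.7, 1.3] restricting
    calls to strains that do not interact in the control screen, and a
    compound-mode synthetic-sick cutoff of S < -0.1.
    """

    fold_threshold: float = 1.3
    q_max: float = 0.05
    s_positive_min: float = 0.3
    s_negative_max: float = -0.3
    control_window: tuple[float, float] = (0.7, 1.3)
    compound_sick_max: float = -0.1

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        lo, hi = self.control_window
        if not lo < hi:
            raise ValueError("control_window lower bound must be below upper")
        if not (self.s_negative_max < 0 < self.s_positive_min):
            raise ValueError("s thresholds must straddle 0")


@dataclass
class ModeratedVariancePrior:
    """Scaled inverse-chi-square prior on per-strain variances."""

    d0: float      # prior degrees of freedom; inf = full shrinkage
    s0_sq: float   # prior variance

    def posterior_variance(self, s_sq, df):
        s_sq = np.asarray(s_sq, dtype=float)
        df = np.asarray(df, dtype=float)
        if math.isinf(self.d0):
            return np.broadcast_to(self.s0_sq, s_sq.shape).copy()
        if self.d0 == 0:
            return s_sq.copy()  # no-moderation limit, exact
        return (self.d0 * self.s0_sq + df * s_sq) / (self.d0 + df)


# ---------------------------------------------------------------------------
# paired differentials
# ---------------------------------------------------------------------------

def replicate_differentials(
    observations: list[ReplicateObservation], query: str
) -> dict[str, np.ndarray]:
    """Per-strain paired log2 differentials for one query.

    Replicates are paired positionally by quadruplicate slot; pairs with a
    missing, flagged or zero area on either side are dropped.  Strains with
    fewer than 2 surviving pairs get an empty array (untestable).
    """
    ind: dict[str, np.ndarray] = {}
    unind: dict[str, np.ndarray] = {}
    for o in observations:
        if o.query_id != query:
            continue
        target = ind if o.condition == INDUCED else unind
        target[o.strain_id] = o.areas
    out: dict[str, np.ndarray] = {}
    for strain in sorted(set(ind) | set(unind)):
        a = ind.get(strain)
        b = unind.get(strain)
        if a is None or b is None:
            out[strain] = np.array([])
            continue
        m = min(len(a), len(b))
        a, b = a[:m], b[:m]
        ok = ~np.isnan(a) & ~np.isnan(b) & (a > 0) & (b > 0)
        d = np.log2(a[ok]) - np.log2(b[ok])
        out[strain] = d if len(d) >= 2 else np.array([])
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def fit_variance_prior(variances, dfs) -> ModeratedVariancePrior:
    """Fit the variance prior by log-moment matching.

    Under the prior, s2 ~ s0^2 * F(df, d0), so log s2 has known mean and
    variance offsets in terms of di/trigamma functions; matching the sample
    mean and variance of the adjusted log variances yields (d0, s0^2).
    A non-positive excess variance (e.g. all variances equal) gives
    d0 = inf with s0^2 the mean variance.
    """
    variances = np.asarray(variances, dtype=float)
    dfs = np.asarray(np.broadcast_to(dfs, variances.shape), dtype=float)
    ok = (dfs >= 1) & np.isfinite(variances) & (variances >= 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 variances with df >= 1")
    if ok.sum() < 50:
        logger.warning("variance prior fitted from only %d strains", int(ok.sum()))
    v, d = variances[ok], dfs[ok]
    if np.all(v == v[0]):
        return ModeratedVariancePrior(d0=math.inf, s0_sq=float(v[0]))
    pos = v > 0
    if pos.sum() < 2:
        return ModeratedVariancePrior(d0=math.inf, s0_sq=float(np.mean(v)))
    v, d = v[pos], d[pos]

    z = np.log(v)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, d / 2.0)))
    if e_var <= 0:
        return ModeratedVariancePrior(d0=math.inf, s0_sq=float(np.mean(v)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedVariancePrior(d0=float(d0), s0_sq=s0_sq)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


# ---------------------------------------------------------------------------
# threshold test
# ---------------------------------------------------------------------------

def threshold_test(
    mean_differential: float,
    s_sq_post: float,
    n_pairs: int,
    prior: ModeratedVariancePrior,
    fold_threshold: float = 1.3,
    null_center: float = 0.0,
) -> tuple[float, float]:
    """Moderated test that |effect - center| exceeds log2(fold_threshold).

    Returns (moderated t statistic, composite-tail p-value).
    """
    tau = math.log2(fold_threshold)
    delta = mean_differential - null_center
    se = math.sqrt(s_sq_post / n_pairs) if s_sq_post > 0 else 0.0
    df = n_pairs - 1 + prior.d0
    if se == 0.0:
        stat = math.inf if delta > 0 else (-math.inf if delta < 0 else 0.0)
        return stat, (0.0 if abs(delta) > tau else 1.0)
    stat = delta / se
    dist = stats.norm if math.isinf(df) else stats.t(df)
    p = float(dist.sf((abs(delta) - tau) / se) + dist.sf((abs(delta) + tau) / se))
    return stat, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-query testing and classification
# ---------------------------------------------------------------------------

def test_query(
    differentials: dict[str, np.ndarray],
    config: TestConfig | None = None,
    prior: ModeratedVariancePrior | None = None,
) -> pd.DataFrame:
    """Run the threshold test over all strains of one query.

    The null center is the median over strains of the per-strain median
    differential.  The variance prior is fitted from this query's sample
    variances unless one is supplied.  q-values are BH-adjusted within the
    query's testable strains.
    """
    cfg = config or TestConfig()
    strains = sorted(differentials)
    means, meds, variances, ns = {}, [], {}, {}
    for s in strains:
        d = differentials[s]
        if len(d) >= 2:
            means[s] = float(np.mean(d))
            variances[s] = float(np.var(d, ddof=1))
            ns[s] = len(d)
            meds.append(float(np.median(d)))
    null_center = float(np.median(meds)) if meds else 0.0

    testable = sorted(means)
    if prior is None and testable:
        prior = fit_variance_prior(
            [variances[s] for s in testable], [ns[s] - 1 for s in testable]
        )

    rows = []
    pvals = []
    for s in strains:
        if s not in means:
            rows.append((s, np.nan, np.nan, 0, np.nan, np.nan))
            continue
        s2_post = float(prior.posterior_variance(variances[s], ns[s] - 1))
        stat, p = threshold_test(
            means[s], s2_post, ns[s], prior, cfg.fold_threshold, null_center
        )
        rows.append((s, means[s], variances[s], ns[s], stat, p))
        pvals.append(p)
    df = pd.DataFrame(
        rows,
        columns=["strain", "log2_differential", "sample_var", "n_pairs",
                 "moderated_stat", "p_value"],
    )
    df["q_value"] = np.nan
    if pvals:
        df.loc[df["p_value"].notna(), "q_value"] = bh_adjust(pvals)
    df.attrs["null_center"] = null_center
    df.attrs["prior"] = prior
    return df


def classify(
    s_scores,
    q_values,
    control_wij,
    usable,
    config: TestConfig | None = None,
) -> np.ndarray:
    """Interaction classes from S, q and the control-query gate.

    A strain is eligible only when its control-query Wij lies in the
    control window (it shows no interaction with the control construct);
    eligible strains are positive when q <= q_max and S > s_positive_min,
    negative when q <= q_max and S < s_negative_max, otherwise none.
    Unusable or ineligible strains are filtered.
    """
    cfg = config or TestConfig()
    s = np.asarray(s_scores, dtype=float)
    q = np.asarray(q_values, dtype=float)
    cw = np.asarray(control_wij, dtype=float)
    ok = np.asarray(usable, dtype=bool)
    lo, hi = cfg.control_window

    out = np.full(s.shape, CLASS_NONE, dtype=object)
    eligible = ok & np.isfinite(cw) & (cw >= lo) & (cw <= hi) & np.isfinite(s) \
        & np.isfinite(q)
    out[~eligible] = CLASS_FILTERED
    sig = eligible & (q <= cfg.q_max)
    out[sig & (s > cfg.s_positive_min)] = CLASS_POSITIVE
    out[sig & (s < cfg.s_negative_max)] = CLASS_NEGATIVE
    return out
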