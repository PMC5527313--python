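"""Synthetic induction screens with planted ground truth.

Emulates a colony-array screen in which each arrayed deletion strain is
pinned in quadruplicate (384 parent positions -> 2x2 blocks on a 1536-format
plate) and grown with or without induction of a query construct.  Colony
areas follow a multiplicative model:

    uninduced:  A = B_x * D_x * T(r, c) * eps
    induced:    A = B_x * D_x * Wi_q * I_xq * T(r, c) * eps

with ``B_x`` a log-normal per-strain baseline, ``D_x`` an optional slow-grower
factor (1 by default), ``Wi_q`` the query-wide induction effect, ``I_xq`` the
planted interaction factor, ``T`` a smooth multiplicative plate surface and
``eps`` log-normal replicate noise with median 1.  The generative counterparts
of the screen statistics are then Wij = Wi_q * I_xq, Wi = Wi_q and
Wj = D_x, so the planted interaction score is Wi_q * (I_xq - Wj).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import INDUCED, UNINDUCED, ArrayLayout, PlateGrid

PARENT_ROWS, PARENT_COLS = 16, 24          # 384 format
CHILD_ROWS, CHILD_COLS = 32, 48            # 1536 format
STRAINS_PER_PLATE = PARENT_ROWS * PARENT_COLS


class SizingError(ValueError):
    """The requested screen does not fit the supported plate geometry."""


def quadruplicate_positions(parent_row: int, parent_col: int) -> set[tuple[int, int]]:
    """2x2 block on the 1536 grid fed by one 384-format parent position."""
    if not (0 <= parent_row < PARENT_ROWS and 0 <= parent_col < PARENT_COLS):
        raise SizingError(
            f"parent position ({parent_row},{parent_col}) outside 16x24 grid"
        )
    r, c = 2 * parent_row, 2 * parent_col
    return {(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)}


@dataclass
class ScreenSimConfig:
    """Study conditions for one simulated screen.

    ``induction_effect_per_query`` lists the true screen-wide induction
    effect Wi for each query; the entry at ``control_query_index`` plays the
    role of the no-interaction control array and receives no planted
    interactions.  ``planted_factor_ranges`` gives one or more (lo, hi)
    ranges from which interaction factors are drawn uniformly; ranges below
    1 plant aggravating (negative-S) interactions, ranges above 1 plant
    alleviating ones.
    """

    n_strains: int
    induction_effect_per_query: tuple[float, ...]
    replicate_count: int = 4
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.15
    planted_fraction: float = 0.0
    planted_factor_ranges: tuple[tuple[float, float], ...] = ((0.3, 0.5), (1.8, 2.2))
    noise_cv: float = 0.1
    outlier_prob: float = 0.0
    outlier_factor: float = 4.0
    missing_prob: float = 0.0
    spatial_gradient_amplitude: float = 0.0
    slow_strain_fraction: float = 0.0
    slow_strain_factor: float = 0.5
    control_query_index: int = 0
    query_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.induction_effect_per_query = tuple(self.induction_effect_per_query)
        self.planted_factor_ranges = tuple(
            tuple(r) for r in self.planted_factor_ranges
        )
        if self.n_strains < 1:
            raise ValueError("n_strains must be positive")
        if self.replicate_count < 2:
            raise ValueError("replicate_count must be >= 2")
        if not self.induction_effect_per_query:
            raise ValueError("need at least one query")
        if any(w <= 0 for w in self.induction_effect_per_query):
            raise ValueError("induction effects must be strictly positive")
        for lo, hi in self.planted_factor_ranges:
            if not (0 < lo <= hi):
                raise ValueError("planted factors must be strictly positive, lo <= hi")
        for name in ("planted_fraction", "outlier_prob", "missing_prob",
                     "slow_strain_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("baseline_log_sd", "noise_cv", "spatial_gradient_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.outlier_factor <= 0 or self.slow_strain_factor <= 0:
            raise ValueError("multiplicative factors must be strictly positive")
        if not (0 <= self.control_query_index < self.n_queries):
            raise ValueError("control_query_index out of range")
        if not self.query_ids:
            ids = []
            for i in range(self.n_queries):
                ids.append("control" if i == self.control_query_index else f"q{i}")
            self.query_ids = tuple(ids)
        if len(self.query_ids) != self.n_queries:
            raise ValueError("query_ids length must match induction effects")

    @property
    def n_queries(self) -> int:
        return len(self.induction_effect_per_query)

    @property
    def control_query_id(self) -> str:
        return self.query_ids[self.control_query_index]


@dataclass
class ScreenTruth:
    """Planted per-(strain, query) ground truth for recovery testing."""

    table: pd.DataFrame  # strain, query, interaction_factor, true_wi, true_wj,
                         # true_s, true_class


def generate_screen(
    config: ScreenSimConfig,
) -> tuple[list[PlateGrid], list[ArrayLayout], ScreenTruth]:
    """Generate all plates of a screen plus its layout(s) and ground truth.

    Returns one induced and one uninduced 1536-format plate per query per
    plate tile (strains beyond 384 spill onto additional tiles); ``layouts``
    has one entry per tile, shared by every query and condition.  Identical
    config and seed produce bit-identical output.
    """
    if config.replicate_count != 4:
        raise SizingError(
            "the 1536-format quadruplicate geometry supports exactly 4 replicates"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    n_tiles = math.ceil(n / STRAINS_PER_PLATE)
    strains = [f"strain{i + 1:05d}" for i in range(n)]

    baselines = np.exp(
        config.baseline_log_mean + config.baseline_log_sd * rng.standard_normal(n)
    )
    slow = np.ones(n)
    if config.slow_strain_fraction > 0:
        slow_mask = rng.random(n) < config.slow_strain_fraction
        slow[slow_mask] = config.slow_strain_factor

    # planted interaction factors, one matrix entry per (strain, query)
    factors = np.ones((n, config.n_queries))
    for qi in range(config.n_queries):
        if qi == config.control_query_index or config.planted_fraction == 0:
            continue
        mask = rng.random(n) < config.planted_fraction
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        which = rng.integers(0, len(config.planted_factor_ranges), size=len(idx))
        lo = np.array([config.planted_factor_ranges[w][0] for w in which])
        hi = np.array([config.planted_factor_ranges[w][1] for w in which])
        factors[idx, qi] = lo + (hi - lo) * rng.random(len(idx))

    layouts = [_tile_layout(strains, t) for t in range(n_tiles)]

    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    plates: list[PlateGrid] = []
    for qi, query in enumerate(config.query_ids):
        wi_q = config.induction_effect_per_query[qi]
        for tile in range(n_tiles):
            for condition in (UNINDUCED, INDUCED):
                # each physical plate gets its own artifact surface
                surface = _plate_surface(rng, config.spatial_gradient_amplitude)
                area = np.full((CHILD_ROWS, CHILD_COLS), np.nan)
                lo_strain = tile * STRAINS_PER_PLATE
                hi_strain = min(n, lo_strain + STRAINS_PER_PLATE)
                for si in range(lo_strain, hi_strain):
                    parent = si - lo_strain
                    pr, pc = divmod(parent, PARENT_COLS)
                    expected = baselines[si] * slow[si]
                    if condition == INDUCED:
                        expected = expected * wi_q * factors[si, qi]
                    positions = sorted(quadruplicate_positions(pr, pc))
                    vals = np.full(4, expected)
                    if sigma > 0:
                        vals = vals * np.exp(sigma * rng.standard_normal(4))
                    if config.outlier_prob > 0 and rng.random() < config.outlier_prob:
                        vals[rng.integers(0, 4)] *= config.outlier_factor
                    for (r, c), v in zip(positions, vals):
                        area[r, c] = v
                if config.missing_prob > 0:
                    gone = rng.random(area.shape) < config.missing_prob
                    area[gone] = np.nan
                area = area * surface
                plates.append(
                    PlateGrid(
                        plate_id=f"{query}|{condition}|tile{tile}",
                        query_id=query,
                        condition=condition,
                        medium="YNB-glucose",
                        area=area,
                    )
                )

    rows = []
    for qi, query in enumerate(config.query_ids):
        wi_q = config.induction_effect_per_query[qi]
        for si, strain in enumerate(strains):
            i_factor = factors[si, qi]
            wj = slow[si]
            true_s = wi_q * (i_factor - wj)
            if i_factor > 1:
                cls = "positive"
            elif i_factor < 1:
                cls = "negative"
            else:
                cls = "none"
            rows.append((strain, query, i_factor, wi_q, wj, true_s, cls))
    truth = ScreenTruth(
        pd.DataFrame(
            rows,
            columns=["strain", "query", "interaction_factor", "true_wi",
                     "true_wj", "true_s", "true_class"],
        )
    )
    return plates, layouts, truth


def plate_layout_pairs(
    plates: list[PlateGrid], layouts: list[ArrayLayout]
) -> list[tuple[PlateGrid, ArrayLayout]]:
    """Pair each generated plate with the layout of its tile."""
    out = []
    for plate in plates:
        tile = int(plate.plate_id.rsplit("tile", 1)[1])
        out.append((plate, layouts[tile]))
    return out


def _tile_layout(strains: list[str], tile: int) -> ArrayLayout:
    lo = tile * STRAINS_PER_PLATE
    hi = min(len(strains), lo + STRAINS_PER_PLATE)
    rows = []
    for si in range(lo, hi):
        parent = si - lo
        pr, pc = divmod(parent, PARENT_COLS)
        for r, c in sorted(quadruplicate_positions(pr, pc)):
            border = r in (0, CHILD_ROWS - 1) or c in (0, CHILD_COLS - 1)
            rows.append((r, c, strains[si], strains[si], border))
    return ArrayLayout(
        pd.DataFrame(rows, columns=["row", "col", "strain", "group", "border"])
    )


def _plate_surface(rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth multiplicative surface with max/min ratio = 1 + amplitude.

    A quadratic polynomial in normalized (row, col) with random coefficients,
    rescaled onto [0, 1] and used as the exponent of (1 + amplitude), so the
    artifact is purely multiplicative and bounded.  Coefficients are drawn
    even when amplitude is 0 so that toggling the artifact does not shift
    the random stream of the remaining noise.
    """
    coef = rng.uniform(-1.0, 1.0, size=5)
    if amplitude == 0:
        return np.ones((CHILD_ROWS, CHILD_COLS))
    u = np.linspace(0.0, 1.0, CHILD_ROWS)[:, None]
    v = np.linspace(0.0, 1.0, CHILD_COLS)[None, :]
    raw = (coef[0] * u + coef[1] * v + coef[2] * u * v
           + coef[3] * u**2 + coef[4] * v**2)
    lo, hi = raw.min(), raw.max()
    g = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return (1.0 + amplitude) ** g
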