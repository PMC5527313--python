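"""Plate normalization and replicate-level filtering.

The scoring statistics are ratios of medians, so all normalization here is
median-based and multiplicative: a missing-aware moving-median surface
removes smooth spatial artifacts, and a single row/column pass removes
residual striping.  Plate-level normalization (forcing all plates to a
common median) is deliberately **not** part of the default pipeline: it
assumes colony-size changes are rare, which is false for induction screens
where the query construct shifts the whole distribution.  Both passes
rescale so the plate median is preserved, keeping areas in their original
units for the low-area filter.

Conventions fixed here so every downstream W statistic is reproducible
bit-for-bit: the median of an even count is the mean of the two central
values (numpy's definition), and the jackknife uses the n-1 sample variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .plate_io import ArrayLayout, PlateGrid

logger = logging.getLogger(__name__)

JACKKNIFE_FLAG = "jackknife"


class NormalizationError(ValueError):
    """Plate too degenerate to normalize (all missing or all zero)."""


@dataclass
class FilterConfig:
    """Replicate-filter settings.

    ``jackknife_fraction``: a replicate is flagged when removing it drops
    more than this fraction of its replicate set's sample variance.
    ``low_area_min_sum``: a strain is dropped when the sum of its induced
    and uninduced median areas falls below this threshold in any screen.
    """

    jackknife_fraction: float = 0.9
    low_area_min_sum: float = 400.0

    def __post_init__(self) -> None:
        if not (0.0 < self.jackknife_fraction <= 1.0):
            raise ValueError("jackknife_fraction must be in (0, 1]")
        if self.low_area_min_sum < 0:
            raise ValueError("low_area_min_sum must be non-negative")


@dataclass
class ReplicateObservation:
    """Post-filter replicate areas for one strain in one plate condition.

    ``areas`` keeps the positional slot structure (NaN where a replicate is
    missing or jackknife-flagged) so induced/uninduced replicates can later
    be paired by pinning slot.
    """

    strain_id: str
    query_id: str
    condition: str
    areas: np.ndarray            # per-slot, NaN = missing/flagged
    n_flagged: int = 0

    @property
    def retained(self) -> np.ndarray:
        return self.areas[~np.isnan(self.areas)]

    @property
    def median_area(self) -> float:
        r = self.retained
        return float(np.median(r)) if len(r) else float("nan")


# ---------------------------------------------------------------------------
# spatial and row/column normalization
# ---------------------------------------------------------------------------

def spatial_normalize(grid: PlateGrid, window: int = 9) -> PlateGrid:
    """Divide by a missing-aware moving-median surface; keep the plate median.

    Each cell is divided by the median of its ``window`` x ``window``
    neighborhood (truncated at plate edges, missing cells ignored) and the
    result is rescaled so the output plate median equals the input plate
    median.  Missing cells stay missing.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    area = grid.area
    finite = ~np.isnan(area)
    if finite.sum() < window * window:
        raise NormalizationError(
            f"plate {grid.plate_id!r}: fewer than {window * window} measured colonies"
        )
    in_median = float(np.nanmedian(area))
    if in_median == 0:
        raise NormalizationError(f"plate {grid.plate_id!r}: plate median is zero")

    with warnings.catch_warnings():
        # windows falling entirely on missing cells are legitimately NaN
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        surface = ndimage.generic_filter(
            area, np.nanmedian, size=window, mode="constant", cval=np.nan
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = area / surface
    ratio[~np.isfinite(ratio) & finite] = np.nan  # local median 0: undefined
    out_median = float(np.nanmedian(ratio))
    if not np.isfinite(out_median) or out_median == 0:
        raise NormalizationError(f"plate {grid.plate_id!r}: degenerate after surface division")
    return grid.copy_with(ratio * (in_median / out_median))


def rowcol_normalize(grid: PlateGrid) -> PlateGrid:
    """One row pass then one column pass of median scaling.

    Each row is divided by (row median / plate median); column medians are
    then recomputed and each column divided likewise; finally the plate is
    rescaled to its original median.  A row or column that is entirely
    missing is left unscaled and logged.
    """
    area = grid.area.copy()
    in_median = float(np.nanmedian(area))
    if not np.isfinite(in_median) or in_median == 0:
        raise NormalizationError(f"plate {grid.plate_id!r}: degenerate plate median")

    for axis, label in ((1, "row"), (0, "col")):
        plate_median = float(np.nanmedian(area))
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
            line_medians = np.nanmedian(area, axis=axis)
        for i, m in enumerate(line_medians):
            if not np.isfinite(m):
                logger.debug("plate %s: %s %d entirely missing, left unscaled",
                             grid.plate_id, label, i + 1)
                continue
            if m == 0:
                logger.warning("plate %s: %s %d median is zero, left unscaled",
                               grid.plate_id, label, i + 1)
                continue
            if axis == 1:
                area[i, :] *= plate_median / m
            else:
                area[:, i] *= plate_median / m
    out_median = float(np.nanmedian(area))
    if out_median != 0 and np.isfinite(out_median):
        area *= in_median / out_median
    return grid.copy_with(area)


def normalize_plate(grid: PlateGrid, window: int = 9,
                    plate_normalize_to: float | None = None) -> PlateGrid:
    """Spatial then row/column normalization (the default preparation).

    ``plate_normalize_to`` optionally forces the plate median to a common
    value afterwards; off by default (see module docstring).
    """
    out = rowcol_normalize(spatial_normalize(grid, window=window))
    if plate_normalize_to is not None:
        med = float(np.nanmedian(out.area))
        if med > 0:
            out = out.copy_with(out.area * (plate_normalize_to / med))
    return out


# ---------------------------------------------------------------------------
# replicate filters
# ---------------------------------------------------------------------------

def jackknife_filter(areas, fraction: float = 0.9) -> np.ndarray:
    """Flag the replicate contributing more than ``fraction`` of the variance.

    Returns a boolean mask aligned with ``areas`` (NaN entries are never
    flagged).  Replicate i's contribution is
    (Var(all) - Var(all \\ i)) / Var(all) with the n-1 sample variance; at
    most one replicate (the maximal contributor) can be flagged, and sets
    with zero variance or fewer than 3 usable replicates are left alone.
    """
    areas = np.asarray(areas, dtype=float)
    flags = np.zeros(areas.shape, dtype=bool)
    usable = np.flatnonzero(~np.isnan(areas))
    if len(usable) < 3:
        logger.debug("jackknife skipped: %d usable replicates", len(usable))
        return flags
    vals = areas[usable]
    var_all = float(np.var(vals, ddof=1))
    if var_all == 0:
        return flags
    contrib = np.empty(len(vals))
    for k in range(len(vals)):
        rest = np.delete(vals, k)
        contrib[k] = (var_all - float(np.var(rest, ddof=1))) / var_all
    best = int(np.argmax(contrib))
    if contrib[best] > fraction:
        flags[usable[best]] = True
    return flags


def low_area_filter(median_induced: float, median_uninduced: float,
                    min_sum: float = 400.0) -> bool:
    """True = keep; drop when the induced+uninduced median-area sum < min_sum."""
    return not (median_induced + median_uninduced < min_sum)


# ---------------------------------------------------------------------------
# plate -> replicate observations
# ---------------------------------------------------------------------------

def collect_observations(
    pairs: list[tuple[PlateGrid, ArrayLayout]],
    filter_config: FilterConfig | None = None,
    *,
    apply_jackknife: bool = True,
) -> list[ReplicateObservation]:
    """Extract per-strain replicate sets from (plate, layout) pairs.

    Replicate slots follow the layout's position order (sorted by row, col)
    so induced and uninduced plates of the same tile pair positionally.
    Jackknife flags are applied per replicate set and recorded both in the
    observation and on the plate's flag grid.
    """
    cfg = filter_config or FilterConfig()
    observations: list[ReplicateObservation] = []
    for plate, layout in pairs:
        for group, positions in layout.positions_by_group().items():
            positions = sorted(positions)
            areas = np.array([plate.area[r, c] for r, c in positions], dtype=float)
            n_flagged = 0
            if apply_jackknife:
                flags = jackknife_filter(areas, cfg.jackknife_fraction)
                n_flagged = int(flags.sum())
                for (r, c), f in zip(positions, flags):
                    if f:
                        plate.flag[r, c] = JACKKNIFE_FLAG
                areas = np.where(flags, np.nan, areas)
            strain = layout.group_strain()[group]
            observations.append(
                ReplicateObservation(
                    strain_id=strain,
                    query_id=plate.query_id,
                    condition=plate.condition,
                    areas=areas,
                    n_flagged=n_flagged,
                )
            )
    return observations


def low_area_drops(
    observations: list[ReplicateObservation],
    min_sum: float = 400.0,
) -> set[str]:
    """Strains failing the low-area filter in *any* screen.

    The returned set is meant to be dropped from every screen scored
    together, so the retained strain set is identical across queries.
    """
    from .plate_io import INDUCED, UNINDUCED

    medians: dict[tuple[str, str, str], float] = {}
    for obs in observations:
        key = (obs.strain_id, obs.query_id, obs.condition)
        medians[key] = obs.median_area
    dropped: set[str] = set()
    queries = {obs.query_id for obs in observations}
    strains = {obs.strain_id for obs in observations}
    for strain in strains:
        for query in queries:
            mi = medians.get((strain, query, INDUCED), float("nan"))
            mu = medians.get((strain, query, UNINDUCED), float("nan"))
            if np.isnan(mi) or np.isnan(mu):
                dropped.add(strain)
                break
            if not low_area_filter(mi, mu, min_sum):
                dropped.add(strain)
                break
    return dropped


def filter_report(
    observations: list[ReplicateObservation], dropped: set[str]
) -> "pd.DataFrame":
    """Tabulate filter outcomes (strain, query, filter, reason)."""
    import pandas as pd

    rows = []
    for obs in observations:
        if obs.n_flagged:
            rows.append((obs.strain_id, obs.query_id, "jackknife",
                         f"{obs.n_flagged} replicate(s) flagged ({obs.condition})"))
    for strain in sorted(dropped):
        rows.append((strain, "*", "low_area", "median-area sum below threshold"))
    return pd.DataFrame(rows, columns=["strain", "query", "filter", "reason"])
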