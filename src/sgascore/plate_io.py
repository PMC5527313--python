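"""Disk formats for colony-array screens.

All on-disk tables are TSV with 1-based plate coordinates; in memory every
grid is a 0-based numpy array.  The conversion happens exactly once, at the
read/write boundary.  Missing colonies are represented by *absent rows* in
the plate table (an area of 0 is a legitimate measurement of a dead spot)
and by NaN cells in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

#: recognised plate formats: name -> (n_rows, n_cols)
PLATE_FORMATS: Mapping[int, tuple[int, int]] = {384: (16, 24), 1536: (32, 48)}

INDUCED = "induced"
UNINDUCED = "uninduced"
CONDITIONS = (INDUCED, UNINDUCED)


class FormatError(ValueError):
    """A file violates the declared on-disk format."""


@dataclass
class PlateGrid:
    """One plate's colony areas on a rows x cols grid.

    ``area`` holds non-negative floats with NaN marking missing colonies;
    ``flag`` holds short string codes ("" = unflagged) aligned with ``area``.
    """

    plate_id: str
    query_id: str
    condition: str
    medium: str
    area: np.ndarray
    flag: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if self.area.ndim != 2:
            raise ValueError("area must be a 2-D grid")
        if self.flag is None:
            self.flag = np.full(self.area.shape, "", dtype=object)
        else:
            self.flag = np.asarray(self.flag, dtype=object)
            if self.flag.shape != self.area.shape:
                raise ValueError("flag grid shape must match area grid")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        with np.errstate(invalid="ignore"):
            if np.any(self.area[~np.isnan(self.area)] < 0):
                raise ValueError("colony areas must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.area.shape[0]

    @property
    def n_cols(self) -> int:
        return self.area.shape[1]

    def copy_with(self, area: np.ndarray) -> "PlateGrid":
        return replace(self, area=np.array(area, dtype=float), flag=self.flag.copy())


@dataclass
class ArrayLayout:
    """Mapping from grid positions to strains and replicate groups."""

    table: pd.DataFrame  # columns: row, col, strain, group, border (0-based)

    def __post_init__(self) -> None:
        t = self.table
        required = ["row", "col", "strain", "group", "border"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"layout missing columns {missing}")
        dup = t.duplicated(subset=["row", "col"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise FormatError(
                f"layout position duplicated at row={t.iloc[i]['row']} col={t.iloc[i]['col']}"
            )
        per_group = t.groupby("group")["strain"].nunique()
        bad = per_group[per_group > 1]
        if len(bad):
            raise FormatError(
                f"replicate group {bad.index[0]!r} maps to {bad.iloc[0]} different strains"
            )

    def positions_by_group(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for row in self.table.itertuples(index=False):
            out.setdefault(row.group, []).append((int(row.row), int(row.col)))
        return out

    def group_strain(self) -> dict[str, str]:
        return dict(zip(self.table["group"], self.table["strain"]))


@dataclass
class ManifestEntry:
    query_id: str
    condition: str
    plate_file: str
    layout_file: str


@dataclass
class ScreenManifest:
    """Pairs induced/uninduced plate files per query and names the control."""

    entries: list[ManifestEntry]
    control_query_id: str

    def __post_init__(self) -> None:
        seen: dict[str, set[str]] = {}
        for e in self.entries:
            if e.condition not in CONDITIONS:
                raise FormatError(f"manifest condition {e.condition!r} invalid")
            seen.setdefault(e.query_id, set()).add(e.condition)
        for q, conds in seen.items():
            if conds != set(CONDITIONS):
                missing = set(CONDITIONS) - conds
                raise FormatError(f"query {q!r} missing {sorted(missing)} plates")
        if self.control_query_id not in seen:
            raise FormatError(
                f"control query {self.control_query_id!r} not among manifest queries"
            )

    @property
    def queries(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.query_id not in out:
                out.append(e.query_id)
        return out

    def files(self, query_id: str, condition: str) -> list[ManifestEntry]:
        return [
            e for e in self.entries if e.query_id == query_id and e.condition == condition
        ]


@dataclass
class ReferenceFDMatrix:
    """Strains x experiments fitness-defect matrix with signature labels."""

    scores: pd.DataFrame  # index strains, columns experiments; NaN allowed
    signatures: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise FormatError("experiment identifiers must be unique")
        if self.signatures is None:
            self.signatures = pd.Series("", index=self.scores.columns)
        else:
            self.signatures = self.signatures.reindex(self.scores.columns).fillna("")


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------

def read_plate_table(
    path,
    declared_format: int,
    *,
    plate_id: str = "",
    query_id: str = "",
    condition: str = UNINDUCED,
    medium: str = "",
) -> PlateGrid:
    """Read a colony-area TSV (``row  col  size  flag``, 1-based) into a PlateGrid.

    Rows absent from the file become missing (NaN) cells.
    """
    n_rows, n_cols = _format_shape(declared_format)
    df = pd.read_csv(path, sep="\t", dtype={"flag": str}, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    for col in ("row", "col", "size"):
        if col not in df.columns:
            raise FormatError(f"{path}: plate table missing column {col!r}")
    if "flag" not in df.columns:
        df["flag"] = ""
    area = np.full((n_rows, n_cols), np.nan)
    flag = np.full((n_rows, n_cols), "", dtype=object)
    seen = set()
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        r, c = int(rec.row) - 1, int(rec.col) - 1
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise FormatError(
                f"{path}:{lineno}: position ({rec.row},{rec.col}) outside "
                f"{declared_format}-format plate"
            )
        if (r, c) in seen:
            raise FormatError(f"{path}:{lineno}: duplicate position ({rec.row},{rec.col})")
        seen.add((r, c))
        size = float(rec.size)
        if np.isnan(size):
            raise FormatError(f"{path}:{lineno}: missing size value")
        if size < 0:
            raise FormatError(f"{path}:{lineno}: negative size {size}")
        area[r, c] = size
        f = rec.flag
        flag[r, c] = "" if (isinstance(f, float) and np.isnan(f)) else str(f)
    return PlateGrid(plate_id=plate_id or str(path), query_id=query_id,
                     condition=condition, medium=medium, area=area, flag=flag)


def write_plate_table(grid: PlateGrid, path) -> None:
    """Inverse of :func:`read_plate_table`; missing cells are omitted."""
    rows = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            a = grid.area[r, c]
            if np.isnan(a):
                continue
            rows.append((r + 1, c + 1, repr(float(a)), grid.flag[r, c]))
    df = pd.DataFrame(rows, columns=["row", "col", "size", "flag"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# layout / manifest / reference matrix
# ---------------------------------------------------------------------------

def read_layout(path) -> ArrayLayout:
    """Read a layout TSV (``row col strain group border``, 1-based coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "group": str},
                     keep_default_na=False, na_values=[""])
    for col in ("row", "col", "strain", "group", "border"):
        if col not in df.columns:
            raise FormatError(f"{path}: layout missing column {col!r}")
    df = df.copy()
    df["row"] = df["row"].astype(int) - 1
    df["col"] = df["col"].astype(int) - 1
    df["border"] = df["border"].astype(int).astype(bool)
    return ArrayLayout(df.reset_index(drop=True))


def write_layout(layout: ArrayLayout, path) -> None:
    df = layout.table.copy()
    df["row"] = df["row"].astype(int) + 1
    df["col"] = df["col"].astype(int) + 1
    df["border"] = df["border"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> ScreenManifest:
    """Read a JSON screen manifest."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        entries = [
            ManifestEntry(rec["query"], rec["condition"], rec["plate_file"],
                          rec["layout_file"])
            for rec in doc["plates"]
        ]
        control = doc["control_query"]
    except KeyError as exc:
        raise FormatError(f"{path}: manifest missing key {exc}") from exc
    return ScreenManifest(entries=entries, control_query_id=control)


def write_manifest(manifest: ScreenManifest, path) -> None:
    doc = {
        "control_query": manifest.control_query_id,
        "plates": [
            {"query": e.query_id, "condition": e.condition,
             "plate_file": e.plate_file, "layout_file": e.layout_file}
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_fd_matrix(path) -> ReferenceFDMatrix:
    """Read a fitness-defect matrix TSV.

    First column is the strain identifier, remaining columns are experiments.
    An optional second header line starting with ``#signature`` carries one
    signature label per experiment.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pos = fh.tell()
        second = fh.readline().rstrip("\n").split("\t")
        signatures = None
        if second and second[0] == "#signature":
            signatures = pd.Series(second[1:], index=header[1:])
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", names=header, index_col=0,
                         na_values=["", "NA"], float_precision="round_trip")
    df = df.astype(float)
    return ReferenceFDMatrix(scores=df, signatures=signatures)


def write_fd_matrix(ref: ReferenceFDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(map(str, ref.scores.columns)) + "\n")
        if (ref.signatures != "").any():
            fh.write("#signature\t" + "\t".join(map(str, ref.signatures)) + "\n")
        ref.scores.to_csv(fh, sep="\t", header=False, na_rep="NA")


def write_results_table(records: pd.DataFrame, path) -> None:
    """Write an interaction-record table (one row per strain x query)."""
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def _format_shape(declared_format: int) -> tuple[int, int]:
    try:
        return PLATE_FORMATS[declared_format]
    except KeyError:
        raise FormatError(
            f"unknown plate format {declared_format}; known: {sorted(PLATE_FORMATS)}"
        ) from None
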