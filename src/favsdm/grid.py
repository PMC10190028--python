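"""Operational geographic units: grid construction, season filtering, presence.

The unit of observation is the OGU, a 1-degree by 1-degree cell of the study
window (default: 20W-60E, 9.5N-70N, the Western Palearctic and surroundings).
Cells are labelled by integer column/row indices counted from the window's
south-west corner, with half-open membership [x, x+size) x [y, y+size) so
every point belongs to exactly one cell.

An OGU table is a plain pandas DataFrame with columns ``ogu_id``, ``lon_idx``,
``lat_idx``, optionally ``presence`` (binary: breeding reported in the cell)
and one numeric column per environmental covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default breeding window, late February to late July (month, day), closed.
BREEDING_WINDOW: tuple[tuple[int, int], tuple[int, int]] = ((2, 21), (7, 31))


@dataclass(frozen=True)
class GridSpec:
    """Rectangular longitude/latitude window tiled with square cells."""

    lon_min: float = -20.0
    lon_max: float = 60.0
    lat_min: float = 9.5
    lat_max: float = 70.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("grid window must have positive extent")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_lon(self) -> int:
        return int(np.ceil((self.lon_max - self.lon_min) / self.cell_size - 1e-9))

    @property
    def n_lat(self) -> int:
        return int(np.ceil((self.lat_max - self.lat_min) / self.cell_size - 1e-9))

    def cell_of(self, lon, lat):
        """Integer (lon_idx, lat_idx) of the cell containing each point."""
        i = np.floor((np.asarray(lon, float) - self.lon_min) / self.cell_size).astype(int)
        j = np.floor((np.asarray(lat, float) - self.lat_min) / self.cell_size).astype(int)
        return i, j

    def contains_cell(self, i, j):
        return (0 <= np.asarray(i)) & (np.asarray(i) < self.n_lon) & \
               (0 <= np.asarray(j)) & (np.asarray(j) < self.n_lat)


def ogu_id(i, j) -> np.ndarray:
    """Canonical string id for cell (lon_idx i, lat_idx j)."""
    return np.char.add(np.char.add(np.asarray(i).astype(str), "_"),
                       np.asarray(j).astype(str))


def build_grid(spec: GridSpec, mask: Iterable[tuple[int, int]] | None = None) -> pd.DataFrame:
    """One row per cell of the window, optionally restricted to a land mask.

    ``mask`` is an iterable of (lon_idx, lat_idx) integer cell labels; cells
    not in the window are rejected, an empty mask is an error.
    """
    if mask is not None:
        cells = sorted(set(tuple(c) for c in mask))
        if not cells:
            raise ValueError("land mask is empty: no OGUs to build")
        ii = np.array([c[0] for c in cells], int)
        jj = np.array([c[1] for c in cells], int)
        if not np.all(spec.contains_cell(ii, jj)):
            bad = [(int(a), int(b)) for a, b in zip(ii, jj) if not spec.contains_cell(a, b)]
            raise ValueError(f"mask cells outside the grid window: {bad[:5]}")
    else:
        ii, jj = np.meshgrid(np.arange(spec.n_lon), np.arange(spec.n_lat), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
    table = pd.DataFrame({"ogu_id": ogu_id(ii, jj), "lon_idx": ii, "lat_idx": jj})
    return table.sort_values(["lon_idx", "lat_idx"], ignore_index=True)


def _month_day(dates: pd.Series) -> np.ndarray:
    d = pd.to_datetime(dates)
    return (d.dt.month * 100 + d.dt.day).to_numpy()


def filter_breeding_season(records: pd.DataFrame,
                           window: tuple[tuple[int, int], tuple[int, int]] = BREEDING_WINDOW,
                           ) -> pd.DataFrame:
    """Keep records whose month-day falls inside the closed window, any year."""
    (m0, d0), (m1, d1) = window
    for m, d in ((m0, d0), (m1, d1)):
        if not (1 <= m <= 12 and 1 <= d <= 31):
            raise ValueError(f"invalid month-day pair ({m}, {d})")
    md = _month_day(records["date"])
    lo, hi = m0 * 100 + d0, m1 * 100 + d1
    keep = (md >= lo) & (md <= hi) if lo <= hi else (md >= lo) | (md <= hi)
    return records.loc[keep].reset_index(drop=True)


def assign_presence(records: pd.DataFrame, grid: pd.DataFrame, spec: GridSpec,
                    training_mask: Iterable[tuple[int, int]] | None = None,
                    ) -> pd.DataFrame:
    """Binary presence per OGU: 1 iff the cell holds >= 1 (season-filtered) record.

    Records falling outside the grid window are counted and logged, never
    fatal. With a training-region mask, presences outside the mask are zeroed
    (the model is trained only on the native range) with a logged warning.
    """
    out = grid.copy()
    i, j = spec.cell_of(records["longitude"].to_numpy(), records["latitude"].to_numpy())
    inside = spec.contains_cell(i, j)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("assign_presence: %d record(s) outside the grid window ignored", n_out)
    hit = set(ogu_id(i[inside], j[inside]).tolist())
    presence = out["ogu_id"].isin(hit).astype(int).to_numpy()
    if training_mask is not None:
        allowed = {ogu_id(a, b).item() for a, b in (tuple(c) for c in training_mask)}
        outside_mask = presence.astype(bool) & ~out["ogu_id"].isin(allowed).to_numpy()
        if outside_mask.any():
            logger.warning(
                "assign_presence: zeroing %d presence cell(s) outside the training region",
                int(outside_mask.sum()))
        presence = np.where(outside_mask, 0, presence)
    out["presence"] = presence
    return out


def zonal_mean(fine: pd.DataFrame, cell_col: str = "ogu_id",
               value_col: str = "value") -> pd.Series:
    """Arithmetic mean of fine-resolution values per cell, ignoring missing.

    Emulates averaging 1 km2 pixels within each OGU. A cell whose values are
    all missing yields NaN and is logged as flagged.
    """
    grouped = fine.groupby(cell_col, sort=True)[value_col].mean()
    empty = grouped.index[grouped.isna()]
    if len(empty):
        logger.warning("zonal_mean: %d cell(s) with no valid value: %s",
                       len(empty), list(empty[:5]))
    return grouped


def presence_counts(table: pd.DataFrame) -> tuple[int, int]:
    """(n1, n0): cells with and without reported breeding."""
    y = table["presence"].to_numpy()
    n1 = int((y == 1).sum())
    return n1, int(len(y) - n1)


def prevalence(table: pd.DataFrame) -> float:
    n1, n0 = presence_counts(table)
    return n1 / (n1 + n0)


def write_ogu_table(table: pd.DataFrame, path) -> None:
    # %.17g round-trips doubles exactly through text
    table.to_csv(path, index=False, float_format="%.17g")


def read_ogu_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    rec["date"] = pd.to_datetime(rec["date"])
    return rec


def grid_geojson(table: pd.DataFrame, spec: GridSpec) -> dict:
    """Cells as GeoJSON polygons (optional mapping export)."""
    feats = []
    for _, row in table.iterrows():
        x = spec.lon_min + row["lon_idx"] * spec.cell_size
        y = spec.lat_min + row["lat_idx"] * spec.cell_size
        s = spec.cell_size
        ring = [[x, y], [x + s, y], [x + s, y + s], [x, y + s], [x, y]]
        props = {k: (row[k].item() if hasattr(row[k], "item") else row[k])
                 for k in table.columns}
        feats.append({"type": "Feature",
                      "geometry": {"type": "Polygon", "coordinates": [ring]},
                      "properties": props})
    return {"type": "FeatureCollection", "features": feats}
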