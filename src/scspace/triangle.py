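"""Holdridge triangle geometry and life-zone classification.

The Holdridge chart arranges life zones as hexagons in an isosceles triangle
whose logarithmic axes are annual precipitation P (62.5 to 16,000 mm, eight
doublings) and the PET ratio R (0.125 to 32, eight doublings).  Normalising
the log2 position on each axis to [0, 1],

    P' = (log2 P - log2 62.5) / 8
    R' = (log2 R - log2 0.125) / 8
    X  = 0.5 * (1 + P' - R')
    Y  = 1 - P' - R'

maps a climate to Cartesian chart coordinates.  Because PET = 58.93 * Tbio,
biotemperature is constant along horizontal lines (constant Y), and the
critical biotemperature lines 1.5/3/6/12/24 degC fall exactly on half-integer
octave diagonals, so zone centroids live on a half-integer log2 lattice.
Within one biotemperature belt, adjacent centroids are separated by exactly
``D0 = 0.125`` in (X, Y) — the unit used to normalise climatic change.

Zones are assigned by nearest centroid in (X, Y); ties go to the lowest zone
id.  Frost resolves the warm-temperate vs subtropical split: the two belts
share chart positions and are distinguished by whether any month records a
minimum temperature at or below 0 degC.  The 38 base zones aggregate to 13
classes through a packaged, overridable table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

from .indicators import PET_PER_BIOTEMP

P_MIN, P_MAX = 62.5, 16000.0
R_MIN, R_MAX = 0.125, 32.0
AXIS_OCTAVES = 8.0

#: (X, Y) distance between two adjacent same-belt zone centroids.
D0 = 0.125

NODATA_ZONE = -1


@dataclass(frozen=True)
class TrianglePoints:
    """Normalised axis positions and Cartesian chart coordinates (arrays)."""

    p_norm: np.ndarray
    r_norm: np.ndarray
    x: np.ndarray
    y: np.ndarray


def to_triangle(P, R) -> TrianglePoints:
    """Place climates on the Holdridge chart.

    ``P`` and ``R`` are clamped to the axis bounds before the log transform,
    keeping hyper-arid and hyper-humid cells classifiable.  Nonpositive or
    NaN inputs yield NaN coordinates (no-data).
    """
    P = np.asarray(P, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~(P > 0) | ~(R > 0)
    Pc = np.clip(P, P_MIN, P_MAX)
    Rc = np.clip(R, R_MIN, R_MAX)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_norm = (np.log2(Pc) - np.log2(P_MIN)) / AXIS_OCTAVES
        r_norm = (np.log2(Rc) - np.log2(R_MIN)) / AXIS_OCTAVES
    p_norm = np.where(bad, np.nan, p_norm)
    r_norm = np.where(bad, np.nan, r_norm)
    x = 0.5 * (1.0 + p_norm - r_norm)
    y = 1.0 - p_norm - r_norm
    return TrianglePoints(p_norm=p_norm, r_norm=r_norm, x=x, y=y)


def triangle_biotemperature(point: TrianglePoints) -> np.ndarray:
    """Biotemperature implied by a chart position, ``R*P / 58.93``.

    Constant along lines of constant Y; used for round-trip checks.
    """
    p = P_MIN * 2.0 ** (AXIS_OCTAVES * point.p_norm)
    r = R_MIN * 2.0 ** (AXIS_OCTAVES * point.r_norm)
    return r * p / PET_PER_BIOTEMP


class ZoneTable:
    """Packaged zone-centroid and aggregation table.

    One row per centroid position; the polar desert spans three lattice
    positions under a single zone id, and the warm-temperate belt appears
    twice (frost / frost-free naming), giving 38 zones in 40 rows.
    """

    REQUIRED = (
        "zone_id", "zone_name", "belt", "frost",
        "p_octave", "r_octave", "agg_id", "agg_name", "color",
    )

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"zone table is missing columns {missing}")
        df = df.sort_values(["zone_id", "p_octave"], kind="stable").reset_index(drop=True)
        if not set(df["frost"]) <= {"any", "frost", "frost_free"}:
            raise ValueError("frost column must be one of any/frost/frost_free")
        self.df = df
        p_norm = df["p_octave"].to_numpy(float) / AXIS_OCTAVES
        r_norm = df["r_octave"].to_numpy(float) / AXIS_OCTAVES
        self._cx = 0.5 * (1.0 + p_norm - r_norm)
        self._cy = 1.0 - p_norm - r_norm

    @classmethod
    def default(cls) -> "ZoneTable":
        path = files("scspace").joinpath("data/holdridge_zones.csv")
        with path.open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "ZoneTable":
        return cls(pd.read_csv(path))

    def candidate_rows(self, frost_free_state: bool) -> np.ndarray:
        """Row indices admissible for a frost state, ordered by zone id."""
        frost = self.df["frost"].to_numpy()
        wanted = "frost_free" if frost_free_state else "frost"
        return np.flatnonzero((frost == "any") | (frost == wanted))

    def centroids_xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self._cx.copy(), self._cy.copy()

    def base_legend(self) -> pd.DataFrame:
        return (
            self.df[["zone_id", "zone_name", "belt", "agg_id"]]
            .drop_duplicates("zone_id")
            .reset_index(drop=True)
        )

    def legend(self) -> pd.DataFrame:
        """Aggregated-class legend: id, name, color."""
        return (
            self.df[["agg_id", "agg_name", "color"]]
            .drop_duplicates("agg_id")
            .sort_values("agg_id")
            .reset_index(drop=True)
        )

    def agg_of_zone(self) -> dict[int, int]:
        return dict(
            self.df[["zone_id", "agg_id"]].drop_duplicates("zone_id").to_numpy()
        )


def classify_zones(x, y, frost_free, table: ZoneTable | None = None,
                   aggregated: bool = True) -> np.ndarray:
    """Assign life zones by nearest centroid on the chart.

    Parameters
    ----------
    x, y
        Chart coordinates (any shape, NaN = no-data).
    frost_free
        Boolean array (broadcastable to ``x``) selecting the subtropical
        (True) or warm-temperate (False) naming for the shared belt.
    aggregated
        Return the 13 aggregated class ids (default) or the 38 base ids.

    Returns
    -------
    int array of zone ids; ``-1`` marks no-data cells.
    """
    if table is None:
        table = ZoneTable.default()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ff = np.broadcast_to(np.asarray(frost_free, dtype=bool), x.shape)

    out = np.full(x.shape, NODATA_ZONE, dtype=np.int64)
    valid = ~(np.isnan(x) | np.isnan(y))
    cx, cy = table.centroids_xy()
    ids = table.df["agg_id" if aggregated else "zone_id"].to_numpy()
    for state in (True, False):
        rows = table.candidate_rows(state)
        sel = valid & (ff == state)
        if not np.any(sel):
            continue
        xs = x[sel][:, None]
        ys = y[sel][:, None]
        d2 = (xs - cx[rows]) ** 2 + (ys - cy[rows]) ** 2
        # rows are ordered by zone id, so argmin's first-hit rule breaks
        # distance ties toward the lowest id
        nearest = rows[np.argmin(d2, axis=1)]
        out[sel] = ids[nearest]
    return out


def zone_areas(zones, areas, table: ZoneTable | None = None) -> pd.DataFrame:
    """Tabulate surface area (km2) per aggregated zone.

    ``zones`` and ``areas`` must be aligned grids; no-data cells (id < 0)
    are excluded.  The returned frame has one row per present zone with its
    legend name where available.
    """
    zones = np.asarray(zones)
    areas = np.asarray(areas, dtype=float)
    if zones.shape != areas.shape:
        raise ValueError(
            f"zone grid {zones.shape} and area grid {areas.shape} are misaligned"
        )
    mask = zones >= 0
    s = pd.Series(areas[mask]).groupby(pd.Series(zones[mask])).sum()
    df = s.rename_axis("zone_id").rename("area_km2").reset_index()
    if table is None:
        table = ZoneTable.default()
    legend = table.legend().rename(columns={"agg_id": "zone_id", "agg_name": "name"})
    df = df.merge(legend[["zone_id", "name"]], on="zone_id", how="left")
    return df[["zone_id", "name", "area_km2"]]
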