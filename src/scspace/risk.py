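"""Production-weighted risk classification.

Couples the magnitude of climatic change with societal resilience:

* livestock headcounts are converted to animal units (AU; 1 AU is roughly
  one adult cow) with fixed per-species coefficients;
* cell surface areas on the regular lat-lon grid follow the spherical-band
  formula, so every percentile here is *area weighted*;
* both the change field and the resilience index are cut into four classes
  (low / moderate / high / very high) at area-weighted 25/50/75th
  percentiles — change thresholds are derived once from a reference
  scenario and reused for others so scenarios stay comparable;
* crop (kcal) and livestock (AU) production are tabulated over the 16
  combined classes, and the high- and critical-risk zones are read off the
  class matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Animal units per head, after Holechek-style range management coefficients.
AU_PER_HEAD = {
    "cattle": 1.0,
    "sheep": 0.15,
    "goats": 0.10,
    "horses": 1.8,
    "buffalo": 0.7,
    "chickens": 0.01,
    "pigs": 0.2,
}

CLASS_LABELS = ("low", "moderate", "high", "very high")
NODATA_CLASS = -1

RISK_OTHER, RISK_HIGH, RISK_CRITICAL = 0, 1, 2
RISK_LABELS = {RISK_OTHER: "other", RISK_HIGH: "high", RISK_CRITICAL: "critical"}


def to_animal_units(headcounts) -> np.ndarray:
    """Convert per-species headcount grids to a single AU grid.

    ``headcounts`` maps species name to a nonnegative array; species must be
    a subset of the seven coefficients in :data:`AU_PER_HEAD`.  Conversion is
    linear, so grids may be summed before or after conversion.
    """
    total = None
    for species, counts in headcounts.items():
        if species not in AU_PER_HEAD:
            raise KeyError(
                f"unknown livestock species {species!r}; expected one of "
                f"{sorted(AU_PER_HEAD)}"
            )
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"negative headcount for species {species!r}")
        part = AU_PER_HEAD[species] * counts
        total = part if total is None else total + part
    if total is None:
        raise ValueError("no species grids supplied")
    return total


def cell_areas(lats, dlat: float, dlon: float, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Surface area (km2) of grid cells centred at the given latitudes.

    Spherical band formula: ``area = R^2 * dlon * (sin(lat+dlat/2) -
    sin(lat-dlat/2))``, exactly proportional to cos(latitude) and symmetric
    about the equator.  ``dlat``/``dlon`` are the cell sizes in degrees.
    """
    lats = np.asarray(lats, dtype=float)
    if np.any(np.abs(lats) > 90):
        raise ValueError("latitudes must lie within [-90, 90]")
    half = np.deg2rad(dlat) / 2.0
    phi = np.deg2rad(lats)
    upper = np.clip(phi + half, -np.pi / 2, np.pi / 2)
    lower = np.clip(phi - half, -np.pi / 2, np.pi / 2)
    return radius**2 * np.deg2rad(dlon) * (np.sin(upper) - np.sin(lower))


def cell_area_grid(lats, lons, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """2-D (lat, lon) area grid from centre coordinates of a regular grid."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    dlat = float(np.abs(np.diff(lats)).mean()) if lats.size > 1 else 1.0
    dlon = float(np.abs(np.diff(lons)).mean()) if lons.size > 1 else 1.0
    band = cell_areas(lats, dlat, dlon, radius=radius)
    return np.repeat(band[:, None], lons.size, axis=1)


@dataclass
class QuantileScheme:
    """Area-weighted class thresholds, reusable across scenarios."""

    thresholds: np.ndarray
    probs: tuple = (0.25, 0.50, 0.75)
    reference: str = ""
    labels: tuple = CLASS_LABELS

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be nondecreasing")
        if len(self.thresholds) != len(self.probs):
            raise ValueError("one threshold per probability required")


def weighted_thresholds(values, weights, probs=(0.25, 0.50, 0.75)) -> np.ndarray:
    """Area-weighted percentile thresholds.

    Each threshold is the smallest field value at which the weighted
    cumulative distribution reaches the target probability.  NaN values (or
    weights) are excluded.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    ok = ~(np.isnan(values) | np.isnan(weights))
    values, weights = values[ok], weights[ok]
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("no valid cells to derive thresholds from")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    idx = np.searchsorted(cw, np.asarray(probs, dtype=float), side="left")
    # searchsorted 'left' returns the first index with cw >= p up to fp noise;
    # nudge past cells whose cumulative mass is still strictly below p
    idx = np.minimum(idx, v.size - 1)
    return v[idx]


def quantile_classes(field_values, areas, scheme: QuantileScheme | None = None,
                     probs=(0.25, 0.50, 0.75), reference: str = ""):
    """Classify a field into area-weighted percentile classes.

    When ``scheme`` is given its thresholds are reused verbatim (the
    reference-scenario rule); otherwise thresholds are derived from the field
    itself.  Class ``k`` collects values in ``(t_{k-1}, t_k]`` (the lowest
    class is everything at or below the first threshold), which makes a
    constant field entirely "low".

    Returns ``(classes, scheme)`` with classes in 0..3 and -1 for no-data.
    """
    field_values = np.asarray(field_values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if field_values.shape != areas.shape:
        raise ValueError("field and area grids are misaligned")
    if scheme is None:
        thr = weighted_thresholds(field_values, areas, probs)
        scheme = QuantileScheme(thresholds=thr, probs=tuple(probs), reference=reference)
    classes = np.zeros(field_values.shape, dtype=np.int64)
    for t in scheme.thresholds:
        classes += (field_values > t).astype(np.int64)
    classes[np.isnan(field_values)] = NODATA_CLASS
    return classes, scheme


@dataclass
class RiskTable:
    """Production shares (%) over the 4x4 change-by-resilience classes."""

    crop: pd.DataFrame
    livestock: pd.DataFrame
    labels: tuple = CLASS_LABELS
    zone_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def share(self, sector: str, change_label: str, resilience_label: str) -> float:
        table = getattr(self, sector)
        return float(table.loc[change_label, resilience_label])


def _share_table(change_cls, resil_cls, production) -> pd.DataFrame:
    total = 0.0
    sums = np.zeros((4, 4))
    valid = (change_cls >= 0) & (resil_cls >= 0) & ~np.isnan(production)
    for i in range(4):
        for j in range(4):
            sel = valid & (change_cls == i) & (resil_cls == j)
            sums[i, j] = production[sel].sum()
    total = sums.sum()
    if total <= 0:
        raise ValueError("no production mass in classified cells")
    return pd.DataFrame(
        100.0 * sums / total, index=list(CLASS_LABELS), columns=list(CLASS_LABELS)
    ).rename_axis(index="change", columns="resilience")


def risk_crosstab(change_cls, resil_cls, crop, livestock_au) -> RiskTable:
    """Tabulate crop and livestock production over the 16 combined classes.

    Cells lacking either classification are excluded; shares are percentages
    of the production mass on classified cells and sum to 100 per sector.
    """
    change_cls = np.asarray(change_cls)
    resil_cls = np.asarray(resil_cls)
    crop = np.asarray(crop, dtype=float)
    livestock_au = np.asarray(livestock_au, dtype=float)
    for grid in (resil_cls, crop, livestock_au):
        if grid.shape != change_cls.shape:
            raise ValueError("risk crosstab inputs are misaligned")
    table = RiskTable(
        crop=_share_table(change_cls, resil_cls, crop),
        livestock=_share_table(change_cls, resil_cls, livestock_au),
    )
    table.zone_table = risk_zone_table()
    return table


def risk_zone_label(change_label: str, resilience_label: str) -> str:
    """Risk zone for one combined class.

    Critical: resilience low and change very high.  High: resilience moderate
    with change very high, or resilience low with change high (very-high
    change cells are already critical — the zones are mutually exclusive).
    """
    if change_label not in CLASS_LABELS or resilience_label not in CLASS_LABELS:
        raise ValueError(
            f"unknown class label ({change_label!r}, {resilience_label!r})"
        )
    if resilience_label == "low" and change_label == "very high":
        return "critical"
    if resilience_label == "moderate" and change_label == "very high":
        return "high"
    if resilience_label == "low" and change_label == "high":
        return "high"
    return "other"


def risk_zone_table() -> pd.DataFrame:
    """Exported 4x4 mapping of combined classes to risk zones."""
    data = {
        r: [risk_zone_label(c, r) for c in CLASS_LABELS] for r in CLASS_LABELS
    }
    return pd.DataFrame(data, index=list(CLASS_LABELS)).rename_axis(
        index="change", columns="resilience"
    )


def risk_zone_grid(change_cls, resil_cls) -> np.ndarray:
    """Per-cell risk zone codes (0 other, 1 high, 2 critical, -1 no-data)."""
    change_cls = np.asarray(change_cls)
    resil_cls = np.asarray(resil_cls)
    out = np.full(change_cls.shape, RISK_OTHER, dtype=np.int64)
    out[(resil_cls == 0) & (change_cls == 2)] = RISK_HIGH
    out[(resil_cls == 1) & (change_cls == 3)] = RISK_HIGH
    out[(resil_cls == 0) & (change_cls == 3)] = RISK_CRITICAL
    out[(change_cls < 0) | (resil_cls < 0)] = NODATA_CLASS
    return out


def resilience_sensitivity(change_cls, resilience, areas, crop, livestock_au,
                           percentiles=range(20, 31)) -> pd.DataFrame:
    """Critical-zone production share as the low-resilience cut varies.

    The change classes stay fixed; for each percentile ``q`` the
    low-resilience set is every cell at or below the area-weighted
    ``q``-th percentile of the resilience index, and the critical zone is
    its intersection with very-high change.  Shares are percentages of total
    production on valid cells; enlarging the low-resilience set can only
    grow them.
    """
    percentiles = list(percentiles)
    if not percentiles:
        raise ValueError("percentile list must not be empty")
    if any(not (0 < q < 50) for q in percentiles):
        raise ValueError("resilience percentiles must lie in (0, 50)")
    change_cls = np.asarray(change_cls)
    resilience = np.asarray(resilience, dtype=float)
    crop = np.asarray(crop, dtype=float)
    livestock_au = np.asarray(livestock_au, dtype=float)
    valid = (change_cls >= 0) & ~np.isnan(resilience)
    rows = []
    for q in percentiles:
        thr = weighted_thresholds(
            np.where(valid, resilience, np.nan), areas, probs=(q / 100.0,)
        )[0]
        critical = valid & (change_cls == 3) & (resilience <= thr)
        rows.append(
            {
                "percentile": q,
                "crop_share": 100.0 * crop[critical].sum() / crop[valid].sum(),
                "livestock_share": 100.0
                * livestock_au[critical].sum()
                / livestock_au[valid].sum(),
            }
        )
    return pd.DataFrame(rows)
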