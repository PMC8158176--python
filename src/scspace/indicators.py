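"""Holdridge climatic indicators from monthly climate.

The Holdridge life-zone system characterises a location's climate with three
annual quantities derived from monthly data:

* annual precipitation ``P`` (mm yr-1), the sum of the twelve monthly totals;
* biotemperature ``Tbio`` (degC), the annual mean of monthly mean temperatures
  with months below 0 degC contributing zero (no upper cap is applied here:
  the 30 degC cap of the original scheme systematically underestimates
  potential evapotranspiration in hot drylands);
* annual potential evapotranspiration ``PET = 58.93 * Tbio`` (mm yr-1) and
  the aridity (PET ratio) ``R = PET / P``.

A cell is *frost free* when the minimum temperature of every month is strictly
above 0 degC; the frost line separates warm-temperate from subtropical zones.

All functions are vectorised over grids: monthly inputs carry the month on
axis 0 (length 12) and any number of trailing spatial dimensions.  Missing
(NaN) monthly values mark the cell's indicators as no-data.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

#: PET accumulated per degree of biotemperature (mm yr-1 degC-1).
PET_PER_BIOTEMP = 58.93

#: Upper bound of the aridity axis; assigned where annual precipitation is 0.
ARIDITY_MAX = 32.0

N_MONTHS = 12


def _monthly(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape[0] != N_MONTHS:
        raise ValueError(
            f"{name} must have {N_MONTHS} months on axis 0, got shape {a.shape}"
        )
    return a


def annual_precipitation(precip) -> np.ndarray:
    """Sum monthly precipitation (mm month-1) into annual totals (mm yr-1).

    NaN in any month propagates to NaN (no-data cell); negative monthly
    values are rejected.
    """
    precip = _monthly(precip, "precip")
    if np.any(precip < 0):
        raise ValueError("monthly precipitation must be nonnegative")
    return precip.sum(axis=0)


def temperature_bias_offsets(tmean_baseline, tmin_baseline, tmax_baseline) -> np.ndarray:
    """Per-cell, per-month additive offsets correcting the min/max midpoint.

    Future scenarios provide only monthly minimum and maximum temperatures, so
    the monthly mean must be approximated by their midpoint.  Where the
    baseline supplies a true monthly mean alongside min and max, the midpoint
    bias is estimated as ``delta_m = mean_m - (tmin_m + tmax_m) / 2`` and can
    be added to future midpoints.
    """
    tmean = _monthly(tmean_baseline, "tmean_baseline")
    tmin = _monthly(tmin_baseline, "tmin_baseline")
    tmax = _monthly(tmax_baseline, "tmax_baseline")
    return tmean - 0.5 * (tmin + tmax)


def monthly_mean_temperature(tmin, tmax, offsets=None) -> np.ndarray:
    """Monthly mean temperature as the min/max midpoint plus optional offsets.

    Cells with ``tmin > tmax`` in any month are flagged invalid (NaN for that
    month).  ``offsets`` (same shape or broadcastable) defaults to zero.
    """
    tmin = _monthly(tmin, "tmin")
    tmax = _monthly(tmax, "tmax")
    tmean = 0.5 * (tmin + tmax)
    bad = tmin > tmax
    if np.any(bad):
        tmean = np.where(bad, np.nan, tmean)
    if offsets is not None:
        tmean = tmean + np.asarray(offsets, dtype=float)
    return tmean


def biotemperature(tmean) -> np.ndarray:
    """Annual biotemperature: mean of monthly means with sub-zero months as 0.

    The divisor stays 12 (zero substitution), so a cell that is frozen all
    year has biotemperature 0 rather than undefined.  No upper cap is applied.
    """
    tmean = _monthly(tmean, "tmean")
    return np.clip(tmean, 0.0, None).mean(axis=0)


def pet(tbio) -> np.ndarray:
    """Annual potential evapotranspiration, ``PET = 58.93 * Tbio`` (mm yr-1)."""
    tbio = np.asarray(tbio, dtype=float)
    if np.any(tbio < 0):
        raise ValueError("biotemperature must be nonnegative")
    return PET_PER_BIOTEMP * tbio


def pet_ratio(pet_annual, p_annual) -> np.ndarray:
    """Aridity: PET divided by annual precipitation.

    Hyper-arid cells with ``P == 0`` are assigned the aridity-axis upper bound
    (32) so that they remain classifiable as desert.
    """
    pet_annual = np.asarray(pet_annual, dtype=float)
    p_annual = np.asarray(p_annual, dtype=float)
    if np.any(pet_annual < 0) or np.any(p_annual < 0):
        raise ValueError("PET and annual precipitation must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(p_annual > 0, pet_annual / p_annual, ARIDITY_MAX)
    # propagate no-data from either input
    r = np.where(np.isnan(pet_annual) | np.isnan(p_annual), np.nan, r)
    return r


def frost_free(tmin) -> np.ndarray:
    """True where every month's minimum temperature is strictly above 0 degC.

    A month at exactly 0 degC counts as frost.  Missing months count as
    frost (conservative); no-data handling for the full indicator set is
    driven by the other variables.
    """
    tmin = _monthly(tmin, "tmin")
    return np.all(tmin > 0.0, axis=0)


def indicators_from_climate(ds: xr.Dataset, bias_offsets=None) -> xr.Dataset:
    """Derive the full indicator set from a monthly-climate dataset.

    Parameters
    ----------
    ds
        Dataset with variables ``prec``, ``tmin``, ``tmax`` dimensioned
        ``(month, lat, lon)`` (month first).
    bias_offsets
        Optional per-cell per-month additive correction for the min/max
        midpoint, as returned by :func:`temperature_bias_offsets`.

    Returns
    -------
    xarray.Dataset
        Variables ``P``, ``tbio``, ``pet``, ``pet_ratio`` (float) and
        ``frost_free`` (bool) on the input's spatial grid; scenario metadata
        attributes are carried over.
    """
    for v in ("prec", "tmin", "tmax"):
        if v not in ds:
            raise ValueError(f"climate dataset is missing variable {v!r}")
    p = annual_precipitation(ds["prec"].values)
    tmean = monthly_mean_temperature(ds["tmin"].values, ds["tmax"].values, bias_offsets)
    tbio = biotemperature(tmean)
    pet_annual = pet(np.where(np.isnan(tbio), 0.0, tbio))
    pet_annual = np.where(np.isnan(tbio), np.nan, pet_annual)
    r = pet_ratio(np.nan_to_num(pet_annual, nan=0.0), np.nan_to_num(p, nan=0.0))
    r = np.where(np.isnan(pet_annual) | np.isnan(p), np.nan, r)
    ff = frost_free(ds["tmin"].values)

    spatial_dims = ds["prec"].dims[1:]
    coords = {d: ds[d] for d in spatial_dims if d in ds.coords}
    out = xr.Dataset(
        {
            "P": (spatial_dims, p),
            "tbio": (spatial_dims, tbio),
            "pet": (spatial_dims, pet_annual),
            "pet_ratio": (spatial_dims, r),
            "frost_free": (spatial_dims, ff),
        },
        coords=coords,
        attrs=dict(ds.attrs),
    )
    return out
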