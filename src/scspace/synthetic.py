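"""Seeded synthetic climate, production, resilience, and country rasters.

The generators emulate the structure of the pipeline's real-world inputs —
WorldClim-style monthly climate normals, per-GCM perturbed futures,
SPAM/GLW3-style production fields, and a smooth [-1, 1] resilience index —
on a coarse regular lat-lon grid with fully known ground truth, so every
downstream stage is testable without external downloads.

Baseline climate combines a latitudinal mean-temperature gradient, a
seasonal cycle whose amplitude grows poleward (phase flipped between
hemispheres), a wet tropics / dry subtropics / moist mid-latitude
precipitation profile, and smooth seeded spatial texture.  Each future GCM
is the baseline plus a per-GCM warming offset, a precipitation multiplier,
and seeded noise (additive Gaussian for temperature, multiplicative
lognormal for precipitation, keeping it positive).  All randomness flows
from a single integer seed; identical specs produce bit-identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter

from . import indicators as ind
from . import scs as scs_mod
from . import triangle as tri

MONTHS = np.arange(1, 13)


@dataclass
class ScenarioSpec:
    """Grid, seed and per-GCM perturbations for one synthetic scenario.

    Defaults describe a high-emissions end-of-century ensemble: eight GCMs
    with end-of-century warming spread 2-5 degC and precipitation scaling
    0.9-1.15, on a 90 x 180 grid spanning 85S-85N (a coarse analogue of the
    5 arc-min grid that still exercises area weighting).
    """

    nlat: int = 90
    nlon: int = 180
    lat_extent: float = 85.0
    seed: int = 0
    n_gcms: int = 8
    warming_offsets: np.ndarray | float | None = None
    precip_multipliers: np.ndarray | float | None = None
    temp_noise: float = 0.3   # degC, monthly
    precip_noise: float = 0.05  # lognormal sigma, fraction of precip
    scenario: str = "highem"

    def __post_init__(self):
        if self.nlat < 2 or self.nlon < 2:
            raise ValueError("grid must be at least 2 x 2 cells")
        if self.n_gcms < 1:
            raise ValueError("at least one GCM required")
        if self.warming_offsets is None:
            self.warming_offsets = np.linspace(2.0, 5.0, self.n_gcms)
        self.warming_offsets = np.broadcast_to(
            np.asarray(self.warming_offsets, dtype=float), (self.n_gcms,)
        ).copy()
        if self.precip_multipliers is None:
            self.precip_multipliers = np.linspace(0.90, 1.15, self.n_gcms)
        self.precip_multipliers = np.broadcast_to(
            np.asarray(self.precip_multipliers, dtype=float), (self.n_gcms,)
        ).copy()
        if np.any(self.precip_multipliers <= 0):
            raise ValueError("precipitation multipliers must be positive")
        if self.temp_noise < 0 or self.precip_noise < 0:
            raise ValueError("noise scales must be nonnegative")

    def coords(self):
        dlat = 2.0 * self.lat_extent / self.nlat
        lats = self.lat_extent - (np.arange(self.nlat) + 0.5) * dlat
        dlon = 360.0 / self.nlon
        lons = -180.0 + (np.arange(self.nlon) + 0.5) * dlon
        return lats, lons


def _smooth_noise(rng, shape, sigma=3.0):
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")


def _baseline_fields(spec: ScenarioSpec):
    lats, lons = spec.coords()
    lat2 = lats[:, None] * np.ones((1, spec.nlon))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))

    # annual-mean temperature: ~28 degC at the equator, ~-12 degC at 85 deg
    t_annual = 28.0 - 43.0 * (lat2 / 90.0) ** 2
    t_annual = t_annual + 1.5 * _smooth_noise(rng, lat2.shape)
    amp = 1.0 + 16.0 * np.abs(lat2) / 90.0  # seasonal amplitude, degC
    hemis = np.sign(lat2)
    dtr = 8.0 + 2.0 * _smooth_noise(rng, lat2.shape)  # diurnal range, degC
    dtr = np.clip(dtr, 1.0, None)

    month_phase = np.cos(2.0 * np.pi * (MONTHS - 7) / 12.0)  # NH peak in July
    tmean = (
        t_annual[None, :, :]
        + amp[None, :, :] * hemis[None, :, :] * month_phase[:, None, None]
    )
    tmin = tmean - dtr[None, :, :] / 2.0
    tmax = tmean + dtr[None, :, :] / 2.0

    # annual precipitation: wet tropics, dry subtropics, moist mid-latitudes
    p_annual = (
        2100.0 * np.exp(-((lat2 / 13.0) ** 2))
        + 750.0 * np.exp(-(((np.abs(lat2) - 48.0) / 14.0) ** 2))
        + 80.0
    )
    p_annual = p_annual * np.exp(0.35 * _smooth_noise(rng, lat2.shape))
    season = 1.0 + 0.5 * hemis[None, :, :] * month_phase[:, None, None]
    season /= season.mean(axis=0, keepdims=True)
    prec = p_annual[None, :, :] / 12.0 * season
    return lats, lons, prec, tmin, tmax


def _dataset(prec, tmin, tmax, lats, lons, **attrs) -> xr.Dataset:
    return xr.Dataset(
        {
            "prec": (("month", "lat", "lon"), prec),
            "tmin": (("month", "lat", "lon"), tmin),
            "tmax": (("month", "lat", "lon"), tmax),
        },
        coords={"month": MONTHS, "lat": lats, "lon": lons},
        attrs=attrs,
    )


def generate_climate(spec: ScenarioSpec):
    """Baseline climate plus one perturbed future per GCM.

    Returns ``(baseline, futures)`` where ``futures`` is a list of
    ``n_gcms`` datasets.  With zero offsets, unit multipliers and zero noise
    each future equals the baseline exactly; warming offsets shift every
    monthly ``tmin``/``tmax`` additively, so ``tmin <= tmax`` always holds.
    """
    lats, lons, prec, tmin, tmax = _baseline_fields(spec)
    baseline = _dataset(prec, tmin, tmax, lats, lons,
                        period="baseline", scenario="baseline", gcm="none")
    futures = []
    for g in range(spec.n_gcms):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + g]))
        dt = spec.warming_offsets[g]
        mult = spec.precip_multipliers[g]
        if spec.temp_noise > 0:
            tshift = dt + spec.temp_noise * np.stack(
                [_smooth_noise(rng, tmin.shape[1:]) for _ in range(12)]
            )
        else:
            tshift = np.full_like(tmin, dt)
        if spec.precip_noise > 0:
            pfac = mult * np.exp(
                spec.precip_noise
                * np.stack([_smooth_noise(rng, prec.shape[1:]) for _ in range(12)])
            )
        else:
            pfac = np.full_like(prec, mult)
        futures.append(
            _dataset(prec * pfac, tmin + tshift, tmax + tshift, lats, lons,
                     period="future", scenario=spec.scenario, gcm=f"gcm{g + 1:02d}")
        )
    return baseline, futures


# global production totals emulated by the default generator
CROP_TOTAL_KCAL = 1.0e13
LIVESTOCK_TOTALS = {
    "cattle": 1.5e9,
    "sheep": 1.2e9,
    "goats": 1.0e9,
    "pigs": 1.0e9,
    "chickens": 2.3e10,
    "horses": 6.0e7,
    "buffalo": 2.0e8,
}


def _suitability(tbio, p_annual, t_opt, t_width, p_opt, p_width):
    with np.errstate(divide="ignore"):
        logp = np.log2(np.clip(p_annual, 1.0, None))
    return np.exp(-(((tbio - t_opt) / t_width) ** 2)) * np.exp(
        -(((logp - np.log2(p_opt)) / p_width) ** 2)
    )


def generate_production(seed: int, climate_indicators: xr.Dataset,
                        concentration: float = 2.0) -> xr.Dataset:
    """Crop (kcal) and livestock headcount grids tied to the climate.

    Production concentrates in mid-range climate cells (warm, moderately
    wet), so a nontrivial safe climatic space exists.  ``concentration``
    sharpens the suitability weighting; as it tends to infinity all mass
    collapses onto the single most suitable cell.
    """
    tbio = np.asarray(climate_indicators["tbio"])
    p_annual = np.asarray(climate_indicators["P"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 100]))

    def weighted(total, suit, texture_sigma=2.5, texture_amp=0.6):
        if np.isinf(concentration):
            w = np.zeros_like(suit)
            w[np.unravel_index(np.argmax(suit), suit.shape)] = 1.0
        else:
            w = suit**concentration
            w = w * np.exp(texture_amp * _smooth_noise(rng, suit.shape, texture_sigma))
        s = w.sum()
        if s <= 0:
            raise ValueError("generated production field is identically zero")
        return total * w / s

    crop = weighted(CROP_TOTAL_KCAL,
                    _suitability(tbio, p_annual, 18.0, 8.0, 1100.0, 1.6))
    grazer_suit = _suitability(tbio, p_annual, 15.0, 11.0, 700.0, 2.4)
    data = {"crop": (("lat", "lon"), crop)}
    for species, total in LIVESTOCK_TOTALS.items():
        data[species] = (("lat", "lon"), weighted(total, grazer_suit))
    return xr.Dataset(
        data,
        coords={
            "lat": climate_indicators["lat"],
            "lon": climate_indicators["lon"],
        },
        attrs={"seed": seed, "concentration": concentration},
    )


def generate_resilience(seed: int, nlat: int, nlon: int,
                        constant: float | None = None) -> np.ndarray:
    """Smooth societal-resilience field in [-1, 1].

    ``constant`` short-circuits to a uniform field (useful for degenerate
    classification tests).
    """
    if constant is not None:
        if not -1.0 <= constant <= 1.0:
            raise ValueError("constant resilience must lie in [-1, 1]")
        return np.full((nlat, nlon), float(constant))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 200]))
    raw = _smooth_noise(rng, (nlat, nlon), sigma=5.0)
    sd = raw.std()
    if sd > 0:
        raw = raw / sd
    return np.tanh(raw)


def generate_countries(seed: int, nlat: int, nlon: int,
                       n_countries: int = 12) -> np.ndarray:
    """Contiguous synthetic country ids (1..n) via nearest seed point."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 300]))
    ci = rng.integers(0, nlat, n_countries)
    cj = rng.integers(0, nlon, n_countries)
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    d2 = (ii[..., None] - ci) ** 2 + (jj[..., None] - cj) ** 2
    return np.argmin(d2, axis=-1) + 1


@dataclass
class GroundTruth:
    """Constructed truth for parameter-recovery tests."""

    fraction: float
    displaced: np.ndarray  # flat cell indices
    requested: float = dc_field(default=float("nan"))


@dataclass
class KnownOutsideScenario:
    baseline: xr.Dataset
    futures: list
    production: xr.Dataset
    ground_truth: GroundTruth


def make_known_outside_scenario(fraction: float, spec: ScenarioSpec | None = None,
                                bins: int = 60, coverage: float = 0.95,
                                n_anchor_bins: int = 12) -> KnownOutsideScenario:
    """Full synthetic dataset whose outside-SCS share is known by design.

    Production is placed only on cells falling in ``n_anchor_bins`` chart
    bins, each holding an equal share of the total mass — every occupied bin
    exceeds the 5% exclusion budget, so the SCS retains all production cells
    and the displaced fraction is recovered without filter bias.  Cells
    carrying mass ``fraction`` of the total then have their future climate
    (all GCMs) moved to the chart apex: annual precipitation at the axis
    lower bound (62.5 mm) and near-zero biotemperature, far outside any
    plausible production cloud.  Undisplaced cells keep the baseline climate
    exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if spec is None:
        spec = ScenarioSpec()
    spec = ScenarioSpec(
        nlat=spec.nlat, nlon=spec.nlon, lat_extent=spec.lat_extent,
        seed=spec.seed, n_gcms=spec.n_gcms, warming_offsets=0.0,
        precip_multipliers=1.0, temp_noise=0.0, precip_noise=0.0,
        scenario="known-outside",
    )
    baseline, futures = generate_climate(spec)
    inds = ind.indicators_from_climate(baseline)
    pts = tri.to_triangle(np.asarray(inds["P"]), np.asarray(inds["pet_ratio"]))

    x_edges = np.linspace(*scs_mod.X_RANGE, bins + 1)
    y_edges = np.linspace(*scs_mod.Y_RANGE, bins + 1)
    ix, iy = scs_mod.bin_indices(pts.x, pts.y, x_edges, y_edges)
    tbio = np.asarray(inds["tbio"])
    p_ann = np.asarray(inds["P"])
    candidate = (
        (ix >= 0) & (tbio > 8.0) & (tbio < 24.0) & (p_ann > 400.0) & (p_ann < 4000.0)
    )
    flat_bin = np.where(candidate, ix * bins + iy, -1).ravel()
    bins_present, counts = np.unique(flat_bin[flat_bin >= 0], return_counts=True)
    if bins_present.size < n_anchor_bins:
        raise ValueError("grid too coarse to anchor the production cloud")
    anchors = bins_present[np.argsort(counts, kind="stable")[::-1][:n_anchor_bins]]

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 400]))
    crop = np.zeros(flat_bin.size)
    for b in anchors:
        cells = np.flatnonzero(flat_bin == b)
        w = rng.lognormal(0.0, 0.3, cells.size)
        crop[cells] = (CROP_TOTAL_KCAL / n_anchor_bins) * w / w.sum()
    total = crop.sum()

    prod_cells = np.flatnonzero(crop > 0)
    target = fraction * total
    cum = 0.0
    displaced = []
    for c in prod_cells:
        if cum < target:
            displaced.append(c)
            cum += crop[c]
        else:
            break
    displaced = np.asarray(displaced, dtype=np.int64)
    actual = crop[displaced].sum() / total if displaced.size else 0.0

    shape2 = (spec.nlat, spec.nlon)
    dis_mask = np.zeros(shape2, dtype=bool)
    dis_mask.ravel()[displaced] = True
    for fut in futures:
        prec = fut["prec"].values
        tmin = fut["tmin"].values
        tmax = fut["tmax"].values
        prec[:, dis_mask] = tri.P_MIN / 12.0   # annual total = 62.5 mm exactly
        tmin[:, dis_mask] = -3.0
        tmax[:, dis_mask] = 4.0                # tmean 0.5 degC -> Tbio 0.5

    lats, lons = spec.coords()
    production = xr.Dataset(
        {
            "crop": (("lat", "lon"), crop.reshape(shape2)),
            "livestock_au": (("lat", "lon"), crop.reshape(shape2) * 1.0e-7),
        },
        coords={"lat": lats, "lon": lons},
        attrs={"seed": spec.seed, "kind": "known-outside"},
    )
    truth = GroundTruth(fraction=float(actual), displaced=displaced,
                        requested=float(fraction))
    return KnownOutsideScenario(baseline=baseline, futures=futures,
                                production=production, ground_truth=truth)
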