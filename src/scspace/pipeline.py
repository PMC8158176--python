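"""End-to-end pipeline orchestration.

Runs the full analysis on one grid: derive Holdridge indicators for the
baseline and every (scenario, GCM) future, classify life zones, measure
chart-space change (ensemble median of the derived variables), cut change
and resilience into area-weighted quartile classes (change thresholds from
the reference scenario, reused elsewhere), tabulate production over the 16
combined risk classes, build the per-sector safe climatic space, and report
outside-SCS shares, likelihood maps and country aggregates.

Inputs are either generated synthetically from the configured seed or read
from pre-supplied NetCDF rasters sharing one grid.  Every stage logs its
parameters and output checksums; stage outputs already on disk are reused
unless ``force`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import change as chg
from . import indicators as ind
from . import io as io_mod
from . import risk as risk_mod
from . import scs as scs_mod
from . import synthetic as synth
from . import triangle as tri
from .config import PipelineConfig

log = logging.getLogger("scspace")


@dataclass
class PipelineResult:
    """In-memory handles to everything the run wrote to disk."""

    config: PipelineConfig
    baseline: xr.Dataset
    futures: dict  # scenario -> list of datasets
    indicators_baseline: xr.Dataset
    zones: np.ndarray
    zone_areas: pd.DataFrame
    change_scheme: risk_mod.QuantileScheme
    change: dict = field(default_factory=dict)       # scenario -> dict
    risk_tables: dict = field(default_factory=dict)  # scenario -> RiskTable
    scs_masks: dict = field(default_factory=dict)    # sector -> SCSMask
    outside: dict = field(default_factory=dict)      # (scenario, sector) -> OutsideShares
    likelihood: dict = field(default_factory=dict)   # (scenario, sector) -> categories
    country_tables: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == out_dir / "pipeline.log"
        for h in log.handlers
    ):
        handler = logging.FileHandler(out_dir / "pipeline.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                              datefmt="%Y-%m-%dT%H:%M:%S")
        )
        log.addHandler(handler)
    log.setLevel(logging.INFO)


def _write_cached(path: Path, writer, force: bool) -> bool:
    """Run ``writer(path)`` unless the output already exists; log either way."""
    if path.exists() and not force:
        log.info("cached: %s", path.name)
        return False
    writer(path)
    log.info("wrote: %s", path.name)
    return True


def _load_inputs(cfg: PipelineConfig):
    """Synthetic generation or file ingestion, behind one interface."""
    if cfg.synthetic:
        futures = {}
        baseline = None
        for name, pert in cfg.scenarios.items():
            spec = synth.ScenarioSpec(
                nlat=cfg.nlat, nlon=cfg.nlon, lat_extent=cfg.lat_extent,
                seed=cfg.seed, n_gcms=cfg.n_gcms,
                warming_offsets=np.asarray(pert["warming"], dtype=float),
                precip_multipliers=np.asarray(pert["precip"], dtype=float),
                scenario=name,
            )
            base, futs = synth.generate_climate(spec)
            baseline = base  # identical across scenarios (same seed/grid)
            futures[name] = futs
        inds = ind.indicators_from_climate(baseline)
        production = synth.generate_production(cfg.seed, inds, cfg.concentration)
        crop = np.asarray(production["crop"])
        livestock_au = risk_mod.to_animal_units(
            {sp: np.asarray(production[sp]) for sp in synth.LIVESTOCK_TOTALS}
        )
        resilience = synth.generate_resilience(cfg.seed, cfg.nlat, cfg.nlon)
        countries = synth.generate_countries(cfg.seed, cfg.nlat, cfg.nlon)
        return baseline, futures, production, crop, livestock_au, resilience, countries

    required = {"baseline", "production", "resilience"}
    missing = required - set(cfg.inputs)
    if missing:
        raise ValueError(f"file-input mode requires input paths {sorted(missing)}")
    baseline = io_mod.read_raster(cfg.inputs["baseline"])
    futures = {}
    for name in cfg.scenarios:
        paths = cfg.inputs.get("futures", {}).get(name, [])
        if len(paths) != cfg.n_gcms:
            raise ValueError(
                f"scenario {name!r}: expected {cfg.n_gcms} future rasters, "
                f"got {len(paths)}"
            )
        futs = []
        for p in paths:
            ds = io_mod.read_raster(p)
            io_mod.assert_aligned(ds, baseline, name=str(p))
            futs.append(ds)
        futures[name] = futs
    production = io_mod.read_raster(cfg.inputs["production"])
    io_mod.assert_aligned(production, baseline, name=str(cfg.inputs["production"]))
    crop = np.asarray(production["crop"])
    if "livestock_au" in production:
        livestock_au = np.asarray(production["livestock_au"])
    else:
        livestock_au = risk_mod.to_animal_units(
            {sp: np.asarray(production[sp])
             for sp in risk_mod.AU_PER_HEAD if sp in production}
        )
    res_ds = io_mod.read_raster(cfg.inputs["resilience"])
    io_mod.assert_aligned(res_ds, baseline, name=str(cfg.inputs["resilience"]))
    resilience = np.asarray(res_ds["resilience"])
    if "countries" in cfg.inputs:
        cty_ds = io_mod.read_raster(cfg.inputs["countries"])
        io_mod.assert_aligned(cty_ds, baseline, name=str(cfg.inputs["countries"]))
        countries = np.asarray(cty_ds["countries"])
    else:
        countries = np.ones((cfg.nlat, cfg.nlon), dtype=np.int64)
    return baseline, futures, production, crop, livestock_au, resilience, countries


def _triangle_of(inds: xr.Dataset) -> tri.TrianglePoints:
    return tri.to_triangle(np.asarray(inds["P"]), np.asarray(inds["pet_ratio"]))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage; deterministic given config + seed."""
    out = Path(cfg.out_dir)
    _setup_logging(out)
    started = datetime.now(timezone.utc).isoformat(timespec="seconds")
    log.info("run started %s seed=%d synthetic=%s", started, cfg.seed, cfg.synthetic)

    # ---- stage: inputs -------------------------------------------------
    try:
        (baseline, futures, production, crop, livestock_au,
         resilience, countries) = _load_inputs(cfg)
    except Exception as err:
        log.error("stage inputs failed: %s", err)
        raise RuntimeError(f"stage 'inputs' failed: {err}") from err

    lats = np.asarray(baseline["lat"])
    lons = np.asarray(baseline["lon"])
    areas = risk_mod.cell_area_grid(lats, lons)
    checksums = {"baseline": io_mod.array_checksum(baseline["prec"].values)}

    if cfg.synthetic:
        _write_cached(out / "baseline.nc",
                      lambda p: io_mod.write_raster(baseline, p), cfg.force)
        _write_cached(out / "production.nc",
                      lambda p: io_mod.write_raster(production, p), cfg.force)
        res_ds = xr.Dataset({"resilience": (("lat", "lon"), resilience)},
                            coords={"lat": lats, "lon": lons})
        _write_cached(out / "resilience.nc",
                      lambda p: io_mod.write_raster(res_ds, p), cfg.force)
        cty_ds = xr.Dataset({"countries": (("lat", "lon"), countries)},
                            coords={"lat": lats, "lon": lons})
        _write_cached(out / "countries.nc",
                      lambda p: io_mod.write_raster(cty_ds, p), cfg.force)
        for name, futs in futures.items():
            for ds in futs:
                fname = f"future_{name}_{ds.attrs['gcm']}.nc"
                _write_cached(out / fname,
                              lambda p, d=ds: io_mod.write_raster(d, p), cfg.force)
    io_mod.write_manifest(out / "manifest.txt", {
        "seed": cfg.seed, "nlat": cfg.nlat, "nlon": cfg.nlon,
        "n_gcms": cfg.n_gcms, "coverage": cfg.coverage, "bins": cfg.bins,
        "reference_scenario": cfg.reference_scenario,
        "resilience_percentile": cfg.resilience_percentile,
        "scenarios": ",".join(cfg.scenarios), "started": started,
    })

    # ---- stage: indicators --------------------------------------------
    try:
        inds_base = ind.indicators_from_climate(baseline)
        offsets = None  # midpoint is exact for synthetic baselines
        inds_fut = {
            name: [ind.indicators_from_climate(ds, offsets) for ds in futs]
            for name, futs in futures.items()
        }
    except Exception as err:
        log.error("stage indicators failed: %s", err)
        raise RuntimeError(f"stage 'indicators' failed: {err}") from err
    _write_cached(out / "indicators_baseline.nc",
                  lambda p: io_mod.write_raster(inds_base, p), cfg.force)
    checksums["indicators"] = io_mod.array_checksum(inds_base["tbio"].values)

    # ---- stage: zones --------------------------------------------------
    try:
        table = tri.ZoneTable.default()
        pts_base = _triangle_of(inds_base)
        zones = tri.classify_zones(pts_base.x, pts_base.y,
                                   np.asarray(inds_base["frost_free"]), table)
        areas_tbl = tri.zone_areas(zones, areas, table)
    except Exception as err:
        log.error("stage zones failed: %s", err)
        raise RuntimeError(f"stage 'zones' failed: {err}") from err
    zones_ds = xr.Dataset({"zone": (("lat", "lon"), zones)},
                          coords={"lat": lats, "lon": lons})
    _write_cached(out / "zones_baseline.nc",
                  lambda p: io_mod.write_raster(zones_ds, p), cfg.force)
    _write_cached(out / "zone_areas.csv",
                  lambda p: areas_tbl.to_csv(p, index=False), cfg.force)
    _write_cached(out / "zone_legend.csv",
                  lambda p: table.legend().to_csv(p, index=False), cfg.force)
    checksums["zones"] = io_mod.array_checksum(zones)

    # ---- stage: change -------------------------------------------------
    try:
        change_results = {}
        magnitudes = {}
        for name, members in inds_fut.items():
            med = chg.ensemble_median_indicators(members)
            pts_fut = tri.to_triangle(med["P"], med["pet_ratio"])
            magnitude = chg.change_magnitude(pts_base, pts_fut)
            direction = chg.change_direction(pts_base, pts_fut)
            change_results[name] = {
                "magnitude": magnitude, "direction": direction, "points": pts_fut,
            }
            magnitudes[name] = magnitude
        ref_scheme = risk_mod.quantile_classes(
            magnitudes[cfg.reference_scenario], areas,
            probs=cfg.quantile_probs, reference=cfg.reference_scenario,
        )[1]
        for name, res in change_results.items():
            res["classes"] = risk_mod.quantile_classes(
                res["magnitude"], areas, scheme=ref_scheme
            )[0]
    except Exception as err:
        log.error("stage change failed: %s", err)
        raise RuntimeError(f"stage 'change' failed: {err}") from err
    for name, res in change_results.items():
        ds = xr.Dataset(
            {
                "magnitude": (("lat", "lon"), res["magnitude"]),
                "direction": (("lat", "lon"), res["direction"]),
                "change_class": (("lat", "lon"), res["classes"]),
            },
            coords={"lat": lats, "lon": lons},
            attrs={"scenario": name, "d0": tri.D0,
                   "threshold_reference": cfg.reference_scenario},
        )
        _write_cached(out / f"change_{name}.nc",
                      lambda p, d=ds: io_mod.write_raster(d, p), cfg.force)
        checksums[f"change_{name}"] = io_mod.array_checksum(res["magnitude"])
    pd.DataFrame({
        "prob": list(ref_scheme.probs), "threshold": list(ref_scheme.thresholds),
    }).pipe(lambda df: _write_cached(
        out / "change_thresholds.csv", lambda p: df.to_csv(p, index=False),
        cfg.force))
    _write_cached(
        out / "direction_legend.csv",
        lambda p: pd.DataFrame(
            sorted(chg.DIRECTION_LABELS.items()), columns=["code", "direction"]
        ).to_csv(p, index=False),
        cfg.force)

    # ---- stage: risk ---------------------------------------------------
    try:
        resil_classes, _ = risk_mod.quantile_classes(resilience, areas,
                                                     probs=cfg.quantile_probs)
        risk_tables = {}
        for name, res in change_results.items():
            rt = risk_mod.risk_crosstab(res["classes"], resil_classes,
                                        crop, livestock_au)
            risk_tables[name] = rt
            zones_grid = risk_mod.risk_zone_grid(res["classes"], resil_classes)
            ds = xr.Dataset(
                {"risk_zone": (("lat", "lon"), zones_grid),
                 "resilience_class": (("lat", "lon"), resil_classes)},
                coords={"lat": lats, "lon": lons}, attrs={"scenario": name},
            )
            _write_cached(out / f"risk_zones_{name}.nc",
                          lambda p, d=ds: io_mod.write_raster(d, p), cfg.force)
            for sector in ("crop", "livestock"):
                _write_cached(
                    out / f"risk_crosstab_{name}_{sector}.csv",
                    lambda p, t=getattr(rt, sector): t.to_csv(p), cfg.force)
            sens = risk_mod.resilience_sensitivity(
                res["classes"], resilience, areas, crop, livestock_au,
                percentiles=range(20, 31),
            )
            _write_cached(out / f"resilience_sensitivity_{name}.csv",
                          lambda p, t=sens: t.to_csv(p, index=False), cfg.force)
        _write_cached(out / "risk_zone_matrix.csv",
                      lambda p: risk_mod.risk_zone_table().to_csv(p), cfg.force)
    except Exception as err:
        log.error("stage risk failed: %s", err)
        raise RuntimeError(f"stage 'risk' failed: {err}") from err

    # ---- stage: scs ----------------------------------------------------
    try:
        sectors = {"crop": crop, "livestock": livestock_au}
        masks, outside, likelihood, country_tables = {}, {}, {}, {}
        for sector, mass in sectors.items():
            mask = scs_mod.build_scs(pts_base.x, pts_base.y, mass,
                                     coverage=cfg.coverage, bins=cfg.bins,
                                     sector=sector)
            masks[sector] = mask
            base_inside = scs_mod.is_inside(mask, pts_base.x, pts_base.y) & (mass > 0)
            for name, members in inds_fut.items():
                fut_xy = [
                    (pts.x, pts.y)
                    for pts in (_triangle_of(m) for m in members)
                ]
                shares = scs_mod.outside_scs_share(
                    fut_xy, mass, mask, (pts_base.x, pts_base.y),
                    filter_future=cfg.filter_future,
                )
                outside[(name, sector)] = shares
                stack = scs_mod.outside_indicator_stack(fut_xy, mask)
                counts, cats = scs_mod.likelihood_map(stack, n_gcms=cfg.n_gcms)
                likelihood[(name, sector)] = cats
                ds = xr.Dataset(
                    {"outside_count": (("lat", "lon"), counts),
                     "likelihood": (("lat", "lon"), cats)},
                    coords={"lat": lats, "lon": lons},
                    attrs={"scenario": name, "sector": sector},
                )
                _write_cached(out / f"likelihood_{name}_{sector}.nc",
                              lambda p, d=ds: io_mod.write_raster(d, p), cfg.force)
                ctable = scs_mod.country_aggregate(cats, stack, mass,
                                                   countries, base_inside)
                country_tables[(name, sector)] = ctable
                _write_cached(out / f"country_{name}_{sector}.csv",
                              lambda p, t=ctable: t.to_csv(p, index=False),
                              cfg.force)
        share_rows = [
            {"scenario": name, "sector": sector,
             "median": s.median, "p5": s.p5, "p95": s.p95,
             **{f"gcm{i + 1:02d}": v for i, v in enumerate(s.per_gcm)}}
            for (name, sector), s in outside.items()
        ]
        _write_cached(out / "outside_scs_shares.csv",
                      lambda p: pd.DataFrame(share_rows).to_csv(p, index=False),
                      cfg.force)
    except Exception as err:
        log.error("stage scs failed: %s", err)
        raise RuntimeError(f"stage 'scs' failed: {err}") from err

    for key, val in checksums.items():
        log.info("checksum %s=%s", key, val)
    log.info("run finished")
    return PipelineResult(
        config=cfg, baseline=baseline, futures=futures,
        indicators_baseline=inds_base, zones=zones, zone_areas=areas_tbl,
        change_scheme=ref_scheme, change=change_results,
        risk_tables=risk_tables, scs_masks=masks, outside=outside,
        likelihood=likelihood, country_tables=country_tables,
        checksums=checksums,
    )
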