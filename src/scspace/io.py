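"""Raster and table I/O plus grid-contract enforcement.

Gridded inputs and outputs travel as NetCDF (classic format, written through
xarray's scipy engine) with dimensions ``(month, lat, lon)`` for monthly
stacks or ``(lat, lon)`` for single fields; tables are CSV.  Coordinates are
cell centres, latitude descending north to south, longitude -180 to 180.

All rasters entering a pipeline run must share one regular lat-lon grid;
nothing is resampled silently — misalignment raises with the offending
file named.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import xarray as xr

SUPPORTED_SUFFIXES = (".nc", ".nc3", ".cdf")


class GridAlignmentError(ValueError):
    """Raised when a raster does not share the pipeline's reference grid."""


def read_raster(path) -> xr.Dataset:
    """Read a NetCDF raster stack.

    Unsupported formats (e.g. GeoTIFF) are rejected with a message naming
    the file rather than guessed at.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported raster format {path.suffix!r} for {path}; "
            f"supported: {', '.join(SUPPORTED_SUFFIXES)}"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        out = ds.load()
    # restore boolean semantics lost to the classic-NetCDF type system
    for name, var in out.data_vars.items():
        if var.attrs.get("scspace_dtype") == "bool":
            out[name] = var.astype(bool)
    return out


def write_raster(ds: xr.Dataset | xr.DataArray, path) -> Path:
    """Write a dataset as classic NetCDF; round-trips values and no-data.

    Integer and float variables round-trip bit-exactly (NaN is the no-data
    marker for floats); booleans are stored as int8 with a marker attribute.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported raster format {path.suffix!r} for {path}; "
            f"supported: {', '.join(SUPPORTED_SUFFIXES)}"
        )
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    enc = ds.copy()
    for name, var in list(enc.data_vars.items()):
        if var.dtype == bool:
            cast = var.astype(np.int8)
            cast.attrs["scspace_dtype"] = "bool"
            enc[name] = cast
        elif var.dtype == np.int64:
            # classic NetCDF has no 64-bit ints; the pipeline's ids fit in 32
            enc[name] = var.astype(np.int32)
    path.parent.mkdir(parents=True, exist_ok=True)
    enc.to_netcdf(path, engine="scipy")
    return path


def assert_aligned(ds: xr.Dataset, reference: xr.Dataset, name: str = "input",
                   atol: float = 1e-8) -> None:
    """Require two datasets to share the lat/lon grid exactly."""
    for coord in ("lat", "lon"):
        if coord not in ds.coords or coord not in reference.coords:
            raise GridAlignmentError(f"{name}: missing {coord} coordinate")
        a = np.asarray(ds[coord])
        b = np.asarray(reference[coord])
        if a.shape != b.shape or not np.allclose(a, b, atol=atol, rtol=0.0):
            raise GridAlignmentError(
                f"{name}: {coord} grid does not match the reference grid "
                "(refusing to resample silently)"
            )


def array_checksum(a) -> str:
    """Stable sha256 of an array's bytes (NaNs included), for run logs."""
    a = np.ascontiguousarray(np.asarray(a))
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]


def write_manifest(path, entries: dict) -> Path:
    """Flat key=value manifest recording seeds and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k}={v}" for k, v in entries.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key] = value
    return out
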