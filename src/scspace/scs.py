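"""Safe climatic space (SCS) construction and membership analysis.

The SCS of a production sector is the region of the Holdridge chart holding
95% of the sector's current production mass.  Production is accumulated into
a regular bin grid over the chart's bounding box, bins are ranked by mass,
and the smallest bins are dropped until just under 5% of the mass has been
excluded — the retained bins form the SCS.  A cell leaves the SCS when its
future chart position (placed per GCM) lands in a non-member bin; shares of
production falling outside are summarised across the GCM ensemble by the
median and the 5th-95th percentile spread, and per-cell GCM agreement is
mapped to likelihood categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

X_RANGE = (0.0, 1.0)
Y_RANGE = (-1.0, 1.0)

LIKELIHOOD_LABELS = {
    0: "very likely inside",
    1: "likely inside",
    2: "potentially outside",
    3: "likely outside",
}


@dataclass
class SCSMask:
    """Binned SCS over the chart: edges, membership, achieved coverage."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    member: np.ndarray  # (nx, ny) bool
    coverage: float
    achieved: float
    sector: str = "crop"
    bin_mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_bins(self) -> tuple[int, int]:
        return self.member.shape


def bin_indices(x, y, x_edges, y_edges):
    """Bin index pair for chart points; -1 where outside the bin grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = np.digitize(x, x_edges) - 1
    iy = np.digitize(y, y_edges) - 1
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    with np.errstate(invalid="ignore"):
        bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny) | np.isnan(x) | np.isnan(y)
    ix = np.where(bad, -1, ix)
    iy = np.where(bad, -1, iy)
    return ix.astype(np.int64), iy.astype(np.int64)


def build_scs(x, y, production, coverage: float = 0.95, bins: int = 60,
              sector: str = "crop") -> SCSMask:
    """Construct the production-weighted SCS.

    Parameters
    ----------
    x, y
        Baseline chart coordinates per cell.
    production
        Nonnegative production mass per cell (kcal or AU), aligned with x/y.
    coverage
        Fraction of production mass the SCS must retain (default 0.95).
    bins
        Number of bins per chart axis over the bounding box
        ``[0, 1] x [-1, 1]``.

    The retained mask is minimal: removing its smallest member bin would
    drop retained mass below the coverage target.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie strictly between 0 and 1")
    production = np.asarray(production, dtype=float)
    x = np.asarray(x, dtype=float)
    if production.shape != x.shape:
        raise ValueError("production grid is misaligned with chart coordinates")
    x_edges = np.linspace(*X_RANGE, bins + 1)
    y_edges = np.linspace(*Y_RANGE, bins + 1)
    ix, iy = bin_indices(x, y, x_edges, y_edges)
    ok = (ix >= 0) & ~np.isnan(production) & (production > 0)
    total = production[ok].sum()
    if total <= 0:
        raise ValueError("total production mass is zero; cannot build an SCS")

    mass = np.zeros((bins, bins))
    np.add.at(mass, (ix[ok], iy[ok]), production[ok])

    flat = mass.ravel()
    order = np.argsort(flat, kind="stable")[::-1]  # descending mass
    cum = np.cumsum(flat[order])
    # retain the heaviest bins until coverage is reached
    k = int(np.searchsorted(cum, coverage * total, side="left")) + 1
    k = min(k, int((flat > 0).sum()))
    member = np.zeros(flat.size, dtype=bool)
    member[order[:k]] = True
    member &= flat > 0
    achieved = flat[member].sum() / total
    return SCSMask(
        x_edges=x_edges,
        y_edges=y_edges,
        member=member.reshape(mass.shape),
        coverage=coverage,
        achieved=float(achieved),
        sector=sector,
        bin_mass=mass,
    )


def is_inside(mask: SCSMask, x, y) -> np.ndarray:
    """Membership of chart points in the SCS (outside the bin grid = False)."""
    ix, iy = bin_indices(x, y, mask.x_edges, mask.y_edges)
    inside = np.zeros(ix.shape, dtype=bool)
    ok = ix >= 0
    inside[ok] = mask.member[ix[ok], iy[ok]]
    return inside


@dataclass
class OutsideShares:
    """Per-GCM outside-SCS production shares with ensemble summary."""

    per_gcm: np.ndarray
    median: float
    p5: float
    p95: float
    denominator_mass: float


def outside_scs_share(future_xy_per_gcm, production, mask: SCSMask,
                      baseline_xy, filter_future: bool = False) -> OutsideShares:
    """Share of major-area production pushed outside the SCS, per GCM.

    The denominator is the production mass of *major production areas*: cells
    whose baseline position lies inside the SCS (the 5% filtered out at
    construction is excluded).  For each GCM the share is the fraction of
    that mass whose future position falls in a non-member bin (or beyond the
    chart bin grid).  Summary statistics are the median and the 5th-95th
    percentile across GCMs.

    With ``filter_future`` the smallest-mass 5% of each GCM's future bin
    cloud is additionally dropped from the numerator (the filter the chart
    densities apply to future conditions); the default keeps the statistic
    conservative.
    """
    production = np.asarray(production, dtype=float)
    xb, yb = baseline_xy
    base_inside = is_inside(mask, xb, yb) & (production > 0)
    denom = production[base_inside].sum()
    if denom <= 0:
        raise ValueError("no production mass inside the baseline SCS")
    shares = []
    for xf, yf in future_xy_per_gcm:
        xf = np.asarray(xf, dtype=float)
        if xf.shape != production.shape:
            raise ValueError("future grid is misaligned with production grid")
        outside = base_inside & ~is_inside(mask, xf, yf)
        if filter_future:
            fmask = build_scs(xf, yf, production, coverage=mask.coverage,
                              bins=mask.n_bins[0], sector=mask.sector)
            outside &= is_inside(fmask, xf, yf)
        shares.append(production[outside].sum() / denom)
    shares = np.asarray(shares)
    return OutsideShares(
        per_gcm=shares,
        median=float(np.median(shares)),
        p5=float(np.percentile(shares, 5)),
        p95=float(np.percentile(shares, 95)),
        denominator_mass=float(denom),
    )


def outside_indicator_stack(future_xy_per_gcm, mask: SCSMask) -> np.ndarray:
    """Boolean (n_gcm, ...) stack: True where a GCM places a cell outside."""
    return np.stack(
        [~is_inside(mask, xf, yf) for xf, yf in future_xy_per_gcm]
    )


def likelihood_map(outside_stack, n_gcms: int = 8):
    """GCM-agreement likelihood of leaving the SCS.

    ``outside_stack`` is one boolean field per GCM.  Categories follow the
    count of models placing the cell outside: 0 -> very likely inside,
    1-3 -> likely inside, 4-6 -> potentially outside, 7-8 -> likely outside.

    Returns ``(counts, categories)``.
    """
    outside_stack = np.asarray(outside_stack, dtype=bool)
    if outside_stack.shape[0] != n_gcms:
        raise ValueError(
            f"expected {n_gcms} GCM indicator fields, got {outside_stack.shape[0]}"
        )
    counts = outside_stack.sum(axis=0)
    categories = np.zeros(counts.shape, dtype=np.int64)
    categories[(counts >= 1) & (counts <= 3)] = 1
    categories[(counts >= 4) & (counts <= 6)] = 2
    categories[counts >= 7] = 3
    return counts, categories


def country_aggregate(categories, outside_stack, production, countries,
                      base_inside) -> pd.DataFrame:
    """National production shares per likelihood category.

    For each country id the production mass in major areas (``base_inside``)
    is split across the four likelihood categories; cells filtered out by
    the 5% rule are reported as ``no_or_minor``.  ``share_outside`` is the
    median across GCMs of the country's outside-SCS production share.
    All shares are percentages of the country's total production mass.
    """
    categories = np.asarray(categories)
    production = np.asarray(production, dtype=float)
    countries = np.asarray(countries)
    base_inside = np.asarray(base_inside, dtype=bool)
    outside_stack = np.asarray(outside_stack, dtype=bool)
    if countries.shape != production.shape:
        raise ValueError("country raster is misaligned with production grid")
    rows = []
    for cid in np.unique(countries[countries >= 0]):
        sel = countries == cid
        total = production[sel].sum()
        if total <= 0:
            continue
        row = {"country": int(cid)}
        inside_sel = sel & base_inside
        for cat, label in LIKELIHOOD_LABELS.items():
            key = label.replace(" ", "_")
            row[key] = 100.0 * production[inside_sel & (categories == cat)].sum() / total
        row["no_or_minor"] = 100.0 * production[sel & ~base_inside].sum() / total
        denom = production[inside_sel].sum()
        if denom > 0:
            per_gcm = [
                production[inside_sel & out].sum() / denom for out in outside_stack
            ]
            row["share_outside"] = 100.0 * float(np.median(per_gcm))
        else:
            row["share_outside"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def plot_triangle_density(mask: SCSMask, future_xy=None, production=None,
                          ax=None):
    """Chart-space view of the SCS (blue bins) and future conditions (red).

    Returns the matplotlib axes; import is deferred so headless use of the
    numerics never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xc = 0.5 * (mask.x_edges[:-1] + mask.x_edges[1:])
    yc = 0.5 * (mask.y_edges[:-1] + mask.y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    ax.scatter(xx[mask.member], yy[mask.member], s=12, marker="s",
               color="#9ecae9", label=f"SCS ({mask.sector})")
    if future_xy is not None:
        xf, yf = future_xy
        w = None if production is None else np.asarray(production, float)
        alpha = 0.25 if w is None else np.clip(w / np.nanmax(w), 0.02, 1.0)
        ax.scatter(np.ravel(xf), np.ravel(yf), s=4, color="crimson",
                   alpha=alpha if np.ndim(alpha) == 0 else None, label="future")
    ax.set_xlabel("X (chart)")
    ax.set_ylabel("Y (chart)")
    ax.set_xlim(*X_RANGE)
    ax.set_ylim(*Y_RANGE)
    ax.legend(loc="lower left", frameon=False)
    return ax
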