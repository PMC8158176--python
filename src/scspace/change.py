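"""Climatic change in Holdridge-chart space.

Change between a baseline and a future climate is the Euclidean displacement
of the cell's chart position, expressed in centroid units: dividing by
``D0 = 0.125`` (the spacing of adjacent same-belt zone centroids) makes a
value of 1 the shift needed to move from the centre of one zone to the next.

The direction of change is reduced to its dominant driver.  In normalised
log units the three axes are linked by ``log2 Tbio = log2 P + log2 R + const``
so the biotemperature component is ``cT = dP' + dR'`` while ``cP = dP'``
(precipitation) and ``cR = dR'`` (aridity).  The driver with the largest
absolute component wins (ties resolved in the order T, R, P) and its sign
picks one of six categories.
"""

from __future__ import annotations

import numpy as np

from .triangle import D0, TrianglePoints

#: Direction category codes; -1 marks no-data.
DIRECTION_LABELS = {
    0: "none",
    1: "warmer",
    2: "cooler",
    3: "wetter",
    4: "drier",
    5: "more arid",
    6: "less arid",
}
NODATA_DIRECTION = -1

_POS = {"T": 1, "P": 3, "R": 5}  # category code for a positive component
_NEG = {"T": 2, "P": 4, "R": 6}


def change_magnitude(base: TrianglePoints, future: TrianglePoints) -> np.ndarray:
    """Chart displacement between two placements, in centroid units.

    Symmetric in its arguments and zero iff the points coincide; NaN in
    either point propagates.
    """
    dx = future.x - base.x
    dy = future.y - base.y
    return np.hypot(dx, dy) / D0


def change_components(base: TrianglePoints, future: TrianglePoints):
    """Driver components ``(cT, cR, cP)`` of a displacement."""
    c_p = future.p_norm - base.p_norm
    c_r = future.r_norm - base.r_norm
    c_t = c_p + c_r
    return c_t, c_r, c_p


def change_direction(base: TrianglePoints, future: TrianglePoints) -> np.ndarray:
    """Dominant-driver direction category for each cell.

    Returns integer codes per :data:`DIRECTION_LABELS`: zero displacement
    maps to ``none`` and swapping the arguments flips each category to its
    opposite (warmer <-> cooler, wetter <-> drier, more <-> less arid).
    """
    c_t, c_r, c_p = change_components(base, future)
    comps = np.stack([c_t, c_r, c_p])  # tie-break priority order T, R, P
    absc = np.abs(comps)
    nodata = np.any(np.isnan(comps), axis=0)
    with np.errstate(invalid="ignore"):
        winner = np.argmax(np.nan_to_num(absc, nan=-1.0), axis=0)
    keys = np.array(["T", "R", "P"])
    win_key = keys[winner]
    win_val = np.take_along_axis(comps, winner[None, ...], axis=0)[0]

    out = np.zeros(win_val.shape, dtype=np.int64)
    for key in keys:
        sel = win_key == key
        out[sel & (win_val > 0)] = _POS[key]
        out[sel & (win_val < 0)] = _NEG[key]
    out[np.all(comps == 0, axis=0)] = 0
    out[nodata] = NODATA_DIRECTION
    return out


def displacement_angle(base: TrianglePoints, future: TrianglePoints) -> np.ndarray:
    """Raw direction of (dX, dY) in radians; companion to the categories."""
    return np.arctan2(future.y - base.y, future.x - base.x)


def ensemble_median(fields, axis: int = 0) -> np.ndarray:
    """Per-cell median across an ensemble of aligned fields.

    ``fields`` is a sequence (or stacked array) of grids of identical shape;
    the even-count median is the mean of the two central order statistics.
    """
    try:
        stack = np.asarray(fields, dtype=float)
    except ValueError as err:
        raise ValueError("ensemble fields are misaligned") from err
    if stack.ndim < 1 or stack.shape[axis] < 1:
        raise ValueError("ensemble must contain at least one field")
    return np.median(stack, axis=axis)


def ensemble_median_indicators(indicator_sets):
    """Median the derived variables (P, Tbio, PET ratio) across GCMs.

    Taking the ensemble median of each climatic variable *before* chart
    placement yields one representative placement per cell; per-GCM
    placements are kept separately for likelihood mapping.

    Parameters
    ----------
    indicator_sets
        Sequence of indicator datasets (as from
        :func:`scspace.indicators.indicators_from_climate`) on one grid.

    Returns
    -------
    dict with keys ``P``, ``tbio``, ``pet_ratio`` holding median arrays.
    """
    if len(indicator_sets) == 0:
        raise ValueError("ensemble must contain at least one member")
    out = {}
    for var in ("P", "tbio", "pet_ratio"):
        stack = np.stack([np.asarray(ds[var]) for ds in indicator_sets])
        out[var] = np.median(stack, axis=0)
    return out
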