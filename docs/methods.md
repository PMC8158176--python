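# Methods

This note records the scientific and numerical choices behind `scspace`,
in the order the pipeline applies them.

## Climatic indicators

Monthly climate enters as precipitation, minimum and maximum temperature
(12 months, mm month⁻¹ / °C). Monthly mean temperature is the min/max
midpoint; where a baseline supplies a true monthly mean alongside min and
max, the midpoint bias is estimated per cell and month as
`δ_m = mean_m − (tmin_m + tmax_m)/2` and added to future midpoints. This
additive form is the simplest correction consistent with estimating means
from min/max pairs; the synthetic generator's truth *is* the midpoint, so
its offsets are zero.

Biotemperature substitutes zero for sub-zero months and keeps the divisor
at 12 (the original Holdridge convention). Dropping frozen months from the
divisor instead would inflate biotemperature toward the poles and misplace
polar cells in the chart. No upper temperature cap is applied: capping at
30 °C systematically underestimates PET in hot drylands relative to
observed evapotranspiration, so hot months contribute at full value.

`PET = 58.93 · Tbio` (mm yr⁻¹). The constant is not arbitrary: it makes
the critical biotemperature lines 1.5/3/6/12/24 °C fall exactly on
half-integer diagonals of the log₂ chart (58.93 · 1.5 = 88.4 ≈ 62.5·√2),
which is what lets zone centroids sit on a regular lattice.

Aridity `R = PET / P`. Cells with `P = 0` get `R = 32` (the axis upper
bound) instead of no-data, keeping hyper-arid cells classifiable as
desert. A cell is frost-free only if *every* month's minimum temperature
is strictly above 0 °C; 0 °C exactly counts as frost.

No-data: any missing monthly input makes all of a cell's indicators
no-data; `tmin > tmax` invalidates that month.

## Chart geometry and zone assignment

Both chart axes span exactly eight doublings (16000/62.5 = 32/0.125 =
2⁸), so the normalisations divide by the constant 8. Writing `p,r` for
octaves above the axis origin, `Y = 1 − (p+r)/8` is constant along lines
of constant biotemperature, and one octave of biotemperature corresponds
to `Δ(p+r) = 1`.

Zone centroids sit at half-integer `(p, r)` on belt diagonals
`p + r = 3, 4, 5, 6, 7, 8` (polar, subpolar, boreal, cool-temperate,
warm-temperate/subtropical, tropical), giving 3+4+5+6+7+8 positions. The
polar belt is a single zone (polar desert) spanning its three positions;
the warm-temperate belt is named twice (warm temperate with frost,
subtropical without), which yields the 38 base zones. Assignment is
nearest centroid in `(X, Y)` with distance ties broken toward the lowest
zone id; the frost flag selects which naming of the shared belt is
admissible. Nearest-centroid assignment reproduces the hexagonal chart
geometry without encoding every hexagon edge.

The 38→13 aggregation ships as an editable CSV
(`scspace/data/holdridge_zones.csv`). It groups by belt and humidity
province — polar desert, tundra, boreal desert/forest, temperate
desert/steppe/forest, subtropical desert/dry forest/forest, tropical
desert/dry forest/forest — with the tropical moist and wet/rain forest
classes merged into one. The belt/humidity grouping pattern is
well-determined; the exact naming of classes not individually named in
published zone maps is this package's choice, and users can override the
table wholesale.

Out-of-range `P` or `R` are clamped to the axis bounds before the log
transform (idempotent; verified by property test), so every physically
valid cell classifies.

## Change metrics

Change magnitude is `‖(ΔX, ΔY)‖ / d₀` with `d₀ = 0.125`. The Cartesian
rendering of the chart is not a perfectly regular hexagonal lattice, so
"distance between two centroids" is not unique; `d₀` is the within-belt
spacing (one octave along one axis at fixed biotemperature), the only
constant spacing in this coordinate system.

The direction of change reduces to its dominant driver. In normalised log
units `cT = ΔP′ + ΔR′` (biotemperature), `cP = ΔP′` (precipitation),
`cR = ΔR′` (aridity); the largest absolute component wins, ties resolved
in the order T, R, P, and the sign picks warmer/cooler, wetter/drier,
more/less arid. Zero displacement maps to "none". The raw displacement
angle is also exposed for users who want the continuous quantity.

For the representative change map the ensemble median is taken over each
derived variable (`P`, `Tbio`, `R`) across GCMs *before* chart placement;
per-GCM placements are kept for the SCS likelihood analysis. Whether to
median variables, coordinates, or final magnitudes is a genuinely open
choice; mediating the physical variables keeps the placed point
physically interpretable, and the convention is isolated in one function
(`ensemble_median_indicators`) should users want another.

## Area weighting and risk classes

Cell areas use the spherical band formula
`A = R² Δλ (sin(φ+Δφ/2) − sin(φ−Δφ/2))`, exactly proportional to
cos(latitude) on a regular grid (Earth radius 6371 km).

Weighted percentile convention: a threshold is the smallest field value
at which the area-weighted cumulative distribution reaches the target
probability; class intervals are right-closed (`value ≤ t₂₅` is "low"),
which makes a constant field entirely "low" and matches the brute-force
weighted-cumulative-sort oracle exactly. Change-class thresholds are
derived once from the reference (low-emissions) scenario and reused for
the others so that scenario maps are comparable; resilience thresholds
are derived from the resilience field itself. Cells with no-data in
either classifier are excluded from thresholds and tabulation.

Risk zones: critical = low resilience ∧ very-high change; high = moderate
resilience ∧ very-high change, or low resilience ∧ high change. Critical
takes precedence, so the zones are mutually exclusive; consumers wanting
the combined "high and critical" total can sum the two. The sensitivity
analysis re-derives the low-resilience cut at the 20th–30th percentiles
with change classes fixed; enlarging the low-resilience set can only
grow the critical share (tested).

Animal units: cattle 1.0, horses 1.8, buffalo 0.7, pigs 0.2, sheep 0.15,
goats 0.10, chickens 0.01 AU head⁻¹. Conversion is linear and rejects
unknown species rather than guessing.

## Safe climatic space

Production mass is histogrammed over a regular 60×60 bin grid spanning
the chart bounding box `[0,1] × [−1,1]`. Bins are ranked by mass and the
smallest dropped until just under 5% of mass is excluded; the retained
set is minimal (dropping its smallest member breaks coverage — tested
for arbitrary coverages and resolutions). Bin resolution is a
configuration knob; 60 per axis keeps parameter-recovery error under the
one-bin tolerance on the default grid while remaining far coarser than
the synthetic grid's chart-position density.

The outside-share statistic: the denominator is the mass of *major
production areas* — cells whose baseline position is inside the SCS; the
numerator is the subset a GCM's future position places in a non-member
bin (or beyond the bin grid). Future positions are placed per GCM (no
ensemble median), and the ensemble is summarised by the median and
5th–95th percentile. The optional `filter_future` switch additionally
drops the smallest 5% of each GCM's future bin cloud from the numerator —
the filter the chart-density visualisation uses; it is off by default
because it can only shrink the statistic. Note that because both
numerator and denominator depend on the mask, the outside share is only
approximately monotone in the coverage target; on the constructed
known-fraction scenario it is monotone and is tested there.

Likelihood categories count GCMs placing a cell outside: 0 very likely
inside, 1–3 likely inside, 4–6 potentially outside, 7–8 likely outside
(eight-member ensembles; the count is validated against the configured
ensemble size). Country aggregation reports each country's production
share per category plus the cells excluded by the 5% filter as "no or
minor production", and the median across GCMs of the country's outside
share.

## Synthetic data

The generator's role is structural realism with known truth, not climate
realism. Baseline: annual-mean temperature 28 °C at the equator falling
quadratically to about −12 °C at 85°, seasonal amplitude growing from 1
to 17 °C poleward with opposite phase by hemisphere, diurnal range ~8 °C;
annual precipitation with a wet tropical band (~2100 mm), dry
subtropics, a secondary mid-latitude maximum (~750 mm) and an 80 mm
floor, modulated by smooth lognormal texture. Futures add a per-GCM
warming offset to every monthly min/max (defaults 2–5 °C across eight
GCMs for the high-emissions ensemble, 0.6–2 °C for the low-emissions
one) and scale precipitation by a per-GCM multiplier (0.90–1.15 /
0.97–1.05), plus smooth additive Gaussian temperature noise (0.3 °C) and
multiplicative lognormal precipitation noise (σ = 0.05), keeping
precipitation positive and `tmin ≤ tmax` exactly. All randomness derives
from one integer seed through independent child streams; identical specs
are bit-identical.

Production concentrates around 18 °C biotemperature / ~1100 mm (crops)
and a broader 15 °C / ~700 mm envelope (livestock, seven species with
plausible global headcount totals), so the crop SCS is smaller than the
livestock SCS, as with real data. Resilience is smoothed noise mapped
through tanh into [−1, 1]; countries are nearest-seed-point tiles.

`make_known_outside_scenario(f)` is the pipeline's oracle: production is
placed only in ~12 chart bins of equal mass (each above the 5% exclusion
budget, so the SCS retains every production cell), and cells carrying
fraction `f` of total mass get their future climate moved to the chart
apex (annual precipitation exactly 62.5 mm, biotemperature 0.5 °C) in
every GCM, far outside any production cloud. The recovered outside share
then equals `f` up to one cell's mass.

What the generator does *not* emulate: GCM spatial covariance, ENSO-like
variability, orography, land/ocean masks, or any spatial correlation
between resilience and development. Passing tests therefore demonstrate
the correctness of the pipeline's operations and conventions, not the
magnitude of real-world risk; the global shares printed in the README's
worked example are properties of the synthetic world.

## Problem sizes and limitations

Default runs use a 90×180 grid (2° cells between 85°S and 85°N), eight
GCMs and two scenarios; the test suite uses grids from 24×48 to 90×180.
These sizes exercise area weighting and ensemble logic while keeping a
full run in seconds.

Known limitations: raster I/O is NetCDF (classic format) and CSV only —
GeoTIFF inputs are rejected with an explicit error; no resampling is
performed (misaligned grids are an error by design); the four future
periods of a full scenario analysis are handled by running the pipeline
once per period; daily-resolution frost statistics and
Penman–Monteith-class PET are out of scope.
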