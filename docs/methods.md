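# Methods

This note documents the models implemented in `canopylight`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
test worlds do and do not establish about real data.

## Input model

Point clouds are classified ALS returns in a projected metric CRS. The
ASPRS convention is assumed: class 2 = ground, classes 3/4/5 = vegetation;
all other codes are carried through but ignored by the metrics. The reader
refuses files whose GeoKey directory declares a geographic (degree) CRS
rather than silently converting. Ground classification itself is out of
scope — the pipeline expects preprocessed data, as is standard practice.

Heights above ground (needed only for area-based cover) come from linear
interpolation over a Delaunay triangulation of the ground returns, with a
nearest-ground fallback outside the triangulation hull. On exactly planar
ground this reproduces the analytic height to ≤ 1e-6 m inside the hull, and
the result is invariant to vertical translation of the whole cloud.

## Hemispherical rendering

The camera sits at a configurable height above ground (default 1 m, the
height of a typical understory survey). All returns within `max_radius`
(default 100 m) are converted to (r, θ, φ) — distance, elevation angle,
azimuth (0 = North, clockwise) — and projected with an equiangular fisheye
mapping: radial pixel distance ∝ zenith angle. The image is oriented as an
upward-looking photograph (North up, East left); a flag flips East–West for
map-style display.

Each vegetation return at or above the camera's horizontal plane is stamped
as a filled disk whose diameter shrinks linearly from 7 px (r = 0) to
0.5 px (r = max_radius). Design decisions here:

- The distance–size anchors are expressed at a **reference side of
  1200 px** and scaled proportionally when rendering at other resolutions,
  so the angular footprint of a marker — and therefore every solid-angle
  metric — is resolution-convergent (tested: DLI and closure move by
  < 0.001 between 600 px and 2400 px).
- The "nearest" anchor is r = 0; the linear law is
  `d(r) = 7 + (0.5 − 7) · r / max_radius`.
- Disks are hard-edged (no anti-aliasing). Sub-pixel disks set the single
  nearest pixel deterministically — a conservative occlusion rule that
  keeps renders reproducible.
- Vegetation below the camera's horizontal plane cannot occlude sky and is
  ignored. Ground returns strictly above the camera are stamped into a
  separate micro-terrain channel with the same marker law, capturing local
  terrain (e.g. an uphill slope) resolved by the point cloud itself.

Macro terrain is handled by a horizon line computed from a coarse DTM
(100-m cells by convention): for each of 360 azimuth bins a ray is marched
from the camera to the grid edge at half-cell steps, and the horizon
elevation is the maximum of `atan2(Δz, distance)`, floored at zero. Every
pixel whose direction lies below this horizon is masked. Rays sample the
nearest cell; with 50–100-m cells the horizon of a smooth ridge is
reproduced to a few tenths of a degree, which is far below the angular
footprint of the masked region itself.

Because true (non-normalized) coordinates are used throughout, canopy on
the uphill side plots nearer the zenith — the geometry that matters in
steep terrain.

## Light indices

Per-pixel solid angle for the equiangular mapping uses the exact Jacobian
`ω ∝ sin ζ / ζ`, whose ζ → 0 limit (1) equals the shrinking zenith cap, so
the center pixel needs no special case beyond the limit value.

**Canopy closure** is the ω-weighted fraction of valid pixels obscured by
any channel. For a uniform horizon mask at elevation h the closed form is
the solid angle of the band ζ ∈ [90° − h, 90°], i.e. `closure = sin h`;
this is the oracle used in the tests (0.259, 0.500, 0.707, 0.866 at
h = 15°, 30°, 45°, 60°).

**Diffuse light** uses the Standard Overcast Sky gradation
`L(ζ)/L_zenith = (1 + b cos ζ)/(1 + b)` with b = 1. Because this angular
shape does not change over time, the seasonal diffuse ratio collapses
exactly to one spatial integral; no time quadrature is needed, and the
overall diffuse magnitude (the "20% of extraterrestrial" convention)
cancels. The closed form for a uniform horizon mask,
`DLI = 1 − (3c² + 2c³)/5` with `c = cos(90° − h)`, verifies the pixel
integration to ±0.005 at 1200 px. The reference sensor is horizontal and
fully open (no terrain in the reference), matching the definition of an
index relative to flat, vegetation-free ground.

**Direct light** integrates the sun's path over the growing season
(days 121–273, i.e. May 1 – September 30, in 10-minute steps of true solar
time). Solar position uses the Spencer Fourier declination series with
standard hour-angle geometry; since everything is expressed in solar time,
longitude and the equation of time drop out. Verified accuracy: ≤ 0.5°
elevation against an independent low-precision almanac ephemeris over 1000
random (latitude, day, time) samples; at 47° N the solstice-noon elevation
is 66.45°. Beam weight per time step is `w = τ^m sin e` with τ = 0.40 at
sea level and m the Kasten–Young air mass times the barometric pressure
ratio `exp(−altitude/8434 m)`; the extraterrestrial constant cancels in the
ratio. Sun-disk visibility v(t) is the unobscured fraction of a fixed
13-point supersampling pattern (5×5 grid clipped to the 0.266°-radius
disk), so even a sub-pixel sun is never lost. Samples that fall below the
image rim count as obscured.

Defaults that are conventions rather than measurements — time step, sun
disk radius, scale height — are all exposed in `RadiationConfig`.

## Canopy cover and plot aggregation

Cover is the count ratio (vegetated first returns with height > 1 m) / (all
first returns) per 4-m cell — an exact rational number, reproduced exactly
on constructed fixtures and invariant to return order. Plot extraction uses
the pixel-center-in-circle rule on circular plots (default 200 m², radius
≈ 7.98 m). Point-based indices are sampled on a √n × √n camera grid
(default 16 points, 4-m mesh) whose centroid coincides with the plot
center, i.e. offsets at ±2 and ±6 m; grid anchoring to the centroid is a
design choice, as is the natural log for the log-transformed summaries
(regression R² is base-invariant). Index values of exactly 0 (possible for
BLI under closed canopies) are floored at 1e-3 before the log and flagged
in the output; plot summaries are means of logs with sd on the log scale
(n − 1 denominator).

## Community statistics

Braun-Blanquet classes map to percent-cover midpoints (r → 0.1, + → 0.5,
1 → 2.5, 2 → 15, 2a → 10, 2b → 20.5, 3 → 37.5, 4 → 62.5, 5 → 87.5); using
ordinal codes as weights instead is a caller-side substitution since the
weighted indicator mean accepts any non-negative weights. Species without a
Landolt value are excluded from both sums of `L_light`. Turnover is the
Simpson dissimilarity on presence–absence (abundances enter only
`L_light`), which is zero for nested pairs by construction.

db-RDA: the dissimilarity matrix is squared, Gower-centered, and
eigendecomposed; axes with negative eigenvalues are dropped (no
Lingoes/Cailliez correction, matching the default of the standard
implementation), and R² is the fitted sum of squares of the least-squares
projection of the positive-axis coordinates onto the centered covariates,
over the positive inertia. Collinear covariate columns are dropped with a
warning (greedy, order-preserving). Adjusted R² is Ezekiel's
`1 − (1 − R²)(n − 1)/(n − p − 1)` with p = number of covariate columns
actually used. The three-group partition computes the 7 union models and
solves the inclusion–exclusion system; raw fractions plus the residual sum
to 1 exactly by construction, and the reporting view floors negative
fractions at zero (they indicate predictors performing worse than random
ones). The implementation is cross-checked in the test suite against R
vegan's `capscale`/`varpart` on random instances (agreement to 1e-6).
Permutation significance tests are intentionally omitted — the analysis
reports variance fractions, not p-values.

## Synthetic worlds

The generators encode the study conditions the pipeline targets:

- **Stands**: Poisson-placed stems (default 400 stems/ha) with solid-cone
  crowns (25 m tall, base at 5 m, 3-m radius — a conifer archetype),
  uniform within-crown return density (0.5 pts/m³) and uniform ground
  returns (8 pts/m²), which together give ≥ 10 returns/m² in a stocked
  stand, the floor for reliable synthetic images. First-return flags go to
  the highest return per 0.5-m column — a simplification of pulse geometry
  that is adequate because cover is a count ratio.
- **Terrain**: planes of given slope/aspect plus Gaussian-profile ridges at
  stated azimuth/distance/height, so horizon angles have closed forms.
- **Communities**: Gaussian niches on a (0, 1] light gradient (default 80
  species, breadth 0.15, lognormal abundance noise σ = 0.5, detection limit
  0.05%), snapped onto the Braun-Blanquet scale and back to midpoints the
  way a survey would record them; species Landolt values derive from their
  niche optima (L = 1 + round(4·optimum)).

Everything is bitwise-deterministic given a seed.

What the synthetic worlds do **not** emulate: within-crown structure
(branches, gaps), leaf-off/leaf-on differences, occlusion-dependent return
density, survey misidentification, or spatial autocorrelation between
plots. Passing tests therefore demonstrate that the geometry, radiometry,
and statistics are implemented correctly — not that the indices are
unbiased on any particular sensor or forest type; applying the tool to a
new ALS campaign still benefits from a one-time comparison with real
hemispherical photographs.

## Problem sizes and numerical notes

The default image side is 1200 px; closed-form checks hold to ±0.005 there,
and the recovery and gradient experiments in the test suite and acceptance
script use 300–600-px renders, 60-m stands, 43-plot communities and 50
replicates — sizes chosen so the full verification runs in a couple of
minutes on one core while leaving every assertion far from its tolerance.
Monotonicity, rotation equivariance (≥ 99% pixel agreement at 90°), and
projection round-trips (≤ 0.5 px) are exercised as properties rather than
point examples.

## Known limitations

- No radiometric realism: returns are opaque disks; intensity,
  transmittance, and leaf optics are ignored, and beam enrichment
  (reflected direct light) is not modeled.
- The macro horizon uses nearest-cell sampling of the DTM; very sharp
  nearby terrain breaks (cliffs within one cell of the camera) are better
  captured by the micro-terrain channel than the horizon line.
- Clear-sky beam transmission is a constant τ^m; no cloud climatology, so
  BLI is a potential (not actual) beam index.
- `L_light` weighting uses converted percent covers; bryophyte handling is
  the caller's choice of input matrix.
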