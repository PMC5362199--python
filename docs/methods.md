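# Methods

This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data tests do and do not
demonstrate.

## Rasters and coordinates

All rasters are north-up, row-major grids of square cells in a projected,
metre-unit CRS; geographic (lon/lat) grids are rejected because the kernel
and zonal computations assume uniform cell area. Two rasters interoperate
only if their grids are exactly equal (alignment is checked before any
cross-raster arithmetic). GeoTIFFs are written through `tifffile` with
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags plus a JSON
ImageDescription carrying the CRS identifier and band/year labels; finite
values round-trip bit-exactly. Mask resampling (e.g. a 250 m land-cover
product onto a 30 m grid) is nearest-neighbour by fine-cell-centre lookup,
which stays well defined for non-integer nesting factors, rather than block
replication.

For desk-scale work the package carries a local equirectangular projection
(`LocalEquirect`): x = R·cos(φ₀)Δλ, y = R·Δφ. Within ±2 km of its centre
the planar distance agrees with the great-circle distance to <0.1%; the
distortion grows with distance from the centre (≈Δy·tanφ₀/R relative error
in the east–west scale), so scenes are laid out centred on the projection
origin. Real deployments at regional scale should substitute a proper
equal-area CRS upstream; everything downstream only assumes "projected,
metres".

## Lichen volume estimate

NDLI = (SWIR1−green)/(SWIR1+green), NDMI = (NIR−SWIR1)/(NIR+SWIR1); a zero
denominator marks the pixel invalid rather than raising. The LVE is a
correlated bivariate Gaussian of the two indices with amplitude A, widths
σ₁, σ₂ > 0 and correlation |ρ| < 1. Defaults (A = 100, centre (0, 0),
σ = 0.25/0.25, ρ = 0) are **placeholders**: the calibrated coefficients
from the original Scandinavian field campaign are not reproduced here, and
any scientific use must supply parameters explicitly. Output is treated as
a relative index; no conversion to physical volume is attempted.

The Gaussian centre defaults to the scene-wide masked index means,
recomputed per year ("scene_mean"); a fixed-centre mode and a single
all-years mean are config switches. Per-year centring follows the annual
processing of the source imagery; fixed centring makes runs exactly
reproducible independent of the mask, which is why the synthetic recipes
use it (see below).

## Temporal trend

Theil–Sen slope: median of all n(n−1)/2 pairwise slopes; even counts
average the two middle values. Mann–Kendall: S = Σ sign differences,
tie-corrected Var(S) = [n(n−1)(2n+5) − Σ tₖ(tₖ−1)(2tₖ+5)]/18, continuity
corrected z, two-sided normal p. The tie and continuity corrections are the
standard definitions; quantised reflectance makes ties real. An all-tied
series returns p = 1 ("no change") instead of dividing by zero.

Pixels are processed on their valid-year subseries; fewer than `min_years`
(default 10) valid years marks the pixel invalid. Classification is
per-pixel at α = 0.05 with **no** multiple-testing correction, matching
common practice for change maps; a Benjamini–Hochberg switch exists but is
off by default. Note that at any α < 1 a pixel with S = 0 exactly (possible
with discrete data or short series) stays "no change" by construction.

The raster path is vectorised (all pairwise differences at once; the tie
term uses the identity that a tie group of size t contributes t(t−1)(2t+5),
equal to summing (c−1)(2c+5) over its elements with c the per-element equal
count) and is tested pixel-for-pixel against the scalar implementation and
against a brute-force oracle.

## Local clustering

G_i* with binary weights over the 3×3 Queen's-case neighbourhood including
the focal pixel, truncated to valid in-bounds neighbours (no padding —
masked tundra rasters are ragged). The mean and standard deviation in the
statistic are global over all valid pixels of the slope raster (divisor n),
so the z-score measures a neighbourhood against the entire image; the
global statistics are computed over lichen-mask pixels only, since only
those carry slopes. Classification is two-sided at z_crit (default 1.96).
A pixel whose neighbourhood is the entire valid set has a 0/0 statistic and
is defined as z = 0.

## Herd-range comparison

Zonal membership is by cell centre in polygon, first polygon wins on
boundary ties — deterministic and conservation-exact: the three class
percentages sum to 100 and counts partition the classified lichen pixels.

Sampling: the herd's bounding box is split into ⌈√n⌉² strata; n draws are
allocated proportional to each stratum's valid-pixel count
(largest-remainder rounding, deterministic tie-break), drawn uniformly
without replacement, fully determined by the seed. The scheme is an
implementation choice for "spatially stratified"; all valid slope pixels
are eligible regardless of significance class.

The herd comparison is a single-factor GLS, slope ~ herd, with errors
either independent or correlated as corr(d) = (1−n₀)·exp(−(d/r)²) (range r,
optional nugget n₀, both estimated). The correlation parameters are
estimated by **REML** by default (`method="ML"` available): in null
simulations with the correlation range comparable to the herd-block size,
plug-in ML left the herd F-test anti-conservative (empirical size ≈0.12 at
α = 0.05), while REML brings it near nominal — the same reason `nlme`
defaults to REML. The likelihood ratio between the spatial and independent
fits is reported under the chosen criterion (the models nest: n₀ → 1
recovers independence, so the LR is nonnegative); the F test uses the
whitened design with k−1 and N−k degrees of freedom. Optimisation is
Nelder–Mead on (log r, logit n₀) from three deterministic starts scaled by
the median pairwise distance.

Tukey HSD uses the studentized range with the GLS covariance of the group
means and N−k residual degrees of freedom; with two groups it reduces
exactly to the unadjusted pairwise test. A residual-semivariogram utility
is provided for spatial-structure diagnostics but is not a gating stage —
the LR comparison plays that role in the pipeline.

## Movement

QC keeps animals with ≥365 consecutive calendar days each carrying at least
`min_fixes_per_day` (default 3) fixes — i.e. a maximum nominal time step of
eight hours, with five-hour collars also admitted. Steps are consecutive
fixes; distance is haversine on a 6,371,000 m sphere; steps with Δt beyond
max_dt (default 8 h) plus a 1 h tolerance are gaps and excluded; velocity
(m/h) puts the two collar schedules on one scale.

Seasons are inclusive month-day windows validated to cover all 366 possible
days exactly once. The defaults — spring Apr 16–Jun 7, summer Jun 8–Sep 7,
fall Sep 8–Nov 30, winter Dec 1–Apr 15 — bracket calving and rut
conventionally and are entirely config-driven, since published season
boundaries for these herds vary. A step belongs to the season and year of
its start fix, and its LVE covariate is read at the start fix (a midpoint
switch exists).

Home ranges are 95% minimum convex polygons: drop the 5% of fixes farthest
from the mean of the projected coordinates, take the convex hull.

## Velocity–LVE smooths

Velocities are rounded to integer m/h so a count family applies — the
overdispersion is in the data regardless of the rounding — and modelled as
NegBin(μ, θ) with log μ = β₀ + s(LVE) + b_animal. s is a cubic B-spline
with 8 basis functions on the observed LVE range under a second
divided-difference penalty evaluated at the Greville abscissae, whose null
space is exactly the linear functions of LVE (so penalty → ∞ collapses the
fit to a GLM line, a tested identity). The sum-to-zero constraint on the
smooth is absorbed by reparameterising onto the orthogonal complement of
the constant direction; the per-animal intercepts are centred dummies
(each row sums to zero) under a ridge penalty, which identifies β₀ as the
population level — predictions with b = 0 are population-mean predictions,
and with a single animal the random-effect block vanishes identically.

Fitting is penalized IRLS with θ re-estimated by profile maximum
likelihood (bounded 1-D search) in an outer loop. The smoothing parameter
is chosen by GCV, n·D/(n−γ·edf)² with γ = 1.4 (the common heavier-edf
guard against undersmoothing), over a fixed log-spaced grid; the animal
ridge defaults to 1.0 on the link scale. The smooth term is tested with a
Wald statistic on the constrained spline block: the Bayesian covariance is
eigendecomposed and the statistic evaluated on the top-variance (i.e.
least-penalized, signal-carrying) directions at rank round(edf_smooth),
referred to χ²; in null simulations on generator output this test runs at
≈4–5% size at α = 0.05. Prediction SEs are delta-method on the response
scale and grow toward the data-sparse tails.

Residual spatial correlation is *not* modelled inside the smooth; the
semivariogram utility can be applied to residuals to examine it. This keeps
the association contract (curve shape + SE) while avoiding a spatially
correlated NB mixed model whose structure the available description leaves
underdetermined; with strong residual spatial correlation the reported
smooth-term p-values will be optimistic, which is a documented limitation.

## Synthetic data

The scene generator inverts the analysis model rather than simulating
radiative transfer, which makes recovery tests sharp: whatever structure is
planted is exactly representable by the pipeline's assumptions.

Per year, a target LVE field is built as baseline + planted cluster trends
× elapsed years + N(0, noise_sd) noise. The baseline is a constant plus a
Gaussian-filtered random surface (clipped into the representable range);
planted trends that would push the deterministic part past the Gaussian
amplitude or below the floor are recipe errors. Each pixel carries a fixed
random phase angle φ; the LVE level set is solved radially — t²(1 − ρ
sin 2φ) = 2(1−ρ²) ln(A/L) — giving an index pair, and band triples (green,
NIR, SWIR1) in (0, 1] are solved in closed form to reproduce both indices
to ~1e-9. Inversion targets the fixed Gaussian centre, so recipes pin
`center_mode="fixed"`; under scene-mean centring the recomputed centre
would drift with the random phases and the planted values would no longer
be exact.

Defaults emulate the study conditions at desk scale: 128×128 pixels,
29 annual epochs (1984–2012), 30 m cells, lichen fraction 0.9, four ±0.5
LVE/yr disk clusters, noise σ = 1 LVE, and two herd polygons (west/east
halves) whose planted trend mixes differ. Movement studies use a variant —
250 m cells (32 km extent), no trend clusters, baseline spatial σ = 12 —
because realistic step lengths (hundreds of m/h over 5–8 h) need room to
move and a wide LVE gradient to sample.

Tracks are correlated random walks: persistent heading with wrapped-normal
turning (σ = 40°), step length ~ NegBin with mean = season response(local
LVE) × Δt and size θ = 5, fix intervals cycling 5 h/8 h over animals,
400 days per animal by default (enough to pass the complete-year QC). If a
drawn step would exit the raster the heading is redrawn uniformly with the
step length kept — reflecting or clamping the endpoint would shorten
realized displacements and bias measured velocities below the planted mean
(this bias was observed and is why reflection is not used). Season
responses: flat; linear decline (1.4→0.5 × base over 0–100 LVE); threshold
decline (flat to L₀, linear decline losing 70% of base by LVE 100); and a
U-shape with its minimum at a configurable LVE. The study-shaped defaults
are spring = linear decline, summer = threshold at 45, fall = U-shape with
minimum at 25, winter = threshold at 25. All randomness flows from a single
recipe seed through `SeedSequence.spawn`.

What passing the synthetic tests shows: the estimators recover structure
that satisfies the model assumptions exactly, at the stated noise levels
and sizes. What it does not show: robustness to sensor artefacts,
compositing residue, phenology, land-cover misclassification, GPS error, or
behaviour (rest/forage/travel states, insect harassment, snow) outside the
velocity–LVE link. Those require real data.

## Problem sizes and calibration conditions

- Trend/cluster recovery: one 128×128 × 29-epoch scene, noise σ = 1;
  median |slope error| ≈ 0.016 LVE/yr, cluster sensitivity 100% of eroded
  interiors, background flag rate ≈1–2%.
- Mann–Kendall size: 2,000 white-noise series of length 29.
- GLS calibration: 3 herds in adjacent 1 km blocks, 50 points each,
  Gaussian range 150 m, nugget 0.25, 500 replicates (200 in the acceptance
  script); the range ≪ domain geometry mirrors sampling 1000 points over
  herd ranges of hundreds of km.
- Smooth recovery: 100 replicates per shape, 5 animals each, one season per
  replicate (45–120 days), on the 250 m movement scene.

## Known limitations

- The LVE coefficients are placeholders; absolute levels are meaningless
  until calibrated.
- The local equirectangular CRS is for desk-scale scenes only.
- No serial-correlation prewhitening in Mann–Kendall (trend tests on
  autocorrelated series are anti-conservative) and no FDR by default —
  both deliberate to match standard change-mapping practice.
- The smooth model omits residual spatial correlation (see above), and the
  Wald smooth test is approximate in the usual penalized-regression sense.
- Shapefile input is not supported; herd polygons are GeoJSON.
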