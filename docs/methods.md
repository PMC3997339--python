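# Methods

`reefcarb` models the carbonate sediment budget of a reef platform that
supports a sand-and-shingle island, and projects that budget through the
21st century under ocean acidification.  Everything runs on synthetic scenes
with known ground truth, so every stage can be verified against the
generating model.  This note records the model, the defaults, and the design
choices that were genuinely open.

## The production model

Net community calcification is computed per raster cell as

    G_net = A_c * k'_r * G_i            [kg CaCO3 m^-2 yr^-1]

with three terms:

**Inorganic aragonite precipitation G_i.**  A power law in the aragonite
saturation state anomaly,

    G_i = k(T) * sign(Omega - 1) * |Omega - 1|^n(T),

zero at saturation and negative in the dissolution regime (a clamp-at-zero
flag is available).  The defaults k = 0.7 kg CaCO3 m^-2 yr^-1 and n = 1.7
are *reconstructions*: they sit in the range reported for abiotic aragonite
precipitation kinetics and for reef net-calcification/Omega fits, but they
are not taken from a published table, and every property of the package
(zero point, monotonicity, signs, calibration, projections) holds for any
monotone law with G_i(1) = 0.  Optional linear temperature sensitivities of
k and n about 25 degC default to zero.  In the pipeline, k is normally not
used at its default at all: it is rescaled so that the start-year budget
matches the contemporary estimate (see Calibration).

**Community calcification fraction A_c.**  For proportional covers P_i of
the four producers with Pacific calcification rates K_c
(branching coral 10, non-branching coral 3, crustose coralline algae 1.49,
*Halimeda* 1.80 kg CaCO3 m^-2 yr^-1),

    A_c = sum_i P_i K_c_i / K_max,      K_max = 10,

so a pixel entirely covered by branching coral — the fastest calcifier —
has A_c = 1.  Covers are planar fractions; all surface-area inflation is
carried by the rugosity term to avoid double counting.

**Rugosity k'_r.**  Ratio of triangulated 3-D surface area to planar area
in a moving window (default 3x3 cells) over the DEM, using the
eight-triangle tessellation around each cell centre.  The tessellation's
projections tile each cell exactly, so a plane tilted at angle theta gives
exactly 1/cos(theta) and a flat surface exactly 1.  Cells with incomplete
windows become nodata rather than being computed from shrunken windows.

Reef-flat and reef-slope cells receive different G_i values through a binary
zone mask (flat = 1), because water ponding over the flat at low tide drives
much larger chemistry excursions there.

## Habitat mapping

Each producer's cover is an OLS linear function of five covariates: two
reflectance bands, depth, slope (degrees, central differences) and rugosity.
Predictions are clipped to [0, 1]; where clipped covers of a cell sum above
1 they are rescaled proportionally (the data never dictate a behaviour for
out-of-range predictions; proportional rescaling preserves composition).
Map accuracy is the coefficient of determination of predicted vs observed
cover at reference points, nearest-cell lookup, no interpolation.  Fits are
rejected with the offending column names when the design is rank deficient.

## The synthetic platform

The generator emulates a ~1.4 km^2 platform: a shallow reef flat
(0.8 m typical depth, ~50% of the area), a ~210 m forereef ramp, and a 15 m
apron, plus smoothed random relief that grows with depth (spur-and-groove
scale roughness).  Reflectance band 2 is an independent smooth field; band 1
is constructed by inverting the log band-ratio bathymetry model
(depth = m1 ln(n b1)/ln(n b2) - m0, defaults m0 = 55, m1 = 60, n = 1000) at
the true depths, then both bands receive 4% multiplicative radiometric
noise — so optical depth retrieval is consistent but not degenerate.

Covers follow the recorded linear model of the five covariates plus
Gaussian patchiness (sd 0.02), clipped to [0, 1] and rescaled where a cell's
sum would exceed 1.  The default coefficients put branching coral on the
deeper, rougher slope, non-branching coral and CCA on the flat, and
*Halimeda* at depth, with per-producer cover standard deviations ~0.11-0.13.
These values were chosen so that (i) covers stay physical everywhere without
noticeable clipping, (ii) a regression fitted to 50 samples with 0.05
observation noise attains a mean map R^2 of ~0.8 (matching what such surveys
achieve in practice), and (iii) transect censuses correlate strongly with
the rate law.  Ground-truth betas are recorded on the scene, so the
noiseless fit-predict round trip is exact to numerical precision.

What the generator does *not* emulate: real satellite radiometry and
atmospheric effects, tides and waves, spatially structured community
patchiness, bioerosion, and carbonate-system speciation (Omega is generated
directly, never derived from DIC/TA).  Passing tests therefore demonstrate
the correctness and statistical behaviour of the method, not the accuracy of
any real-world map.

## Hydrochemistry and the Omega trajectory

The decadal trajectory interpolates reef-flat Omega from a year-2000 annual
mean of 3.2 (diurnal limits 4.1/2.4, seasonal offsets +-0.15) to the
end-century values mean 2.13 with diurnal limits 3.95 and 0.85.  The decline
is exponential-accelerating by default (year-on-year decrements strictly
increasing, tracking CO2 growth under a high-emissions pathway); a linear
shape is available.  The year-2000 baseline is an assumption — no seasonal
baseline is published for the site — and is fully configurable.

The reef slope declines by a fraction 0.6 of the flat's decline.  Rationale:
ponding isolates and amplifies acidification in reef-flat water, while slope
water tracks milder offshore conditions; the slope's larger share of
production then damps the flat's nonlinearity, which is also why the
projected volume series is near-linear even though Omega declines
exponentially.

A tidal-cycle series (default 7 h window, 0.5 h steps) oscillates around the
seasonal mean: half-amplitude 1.2 Omega units on the flat (the ponding
excursion) and 0.3 of that on the slope, capped by the year's diurnal
limits, with small Gaussian noise; the series is recentred so its
trapezoidal time-weighted mean equals the seasonal mean exactly.  G_i for a
zone and season is the trapezoidal mean of the rate law over this series;
the four seasons are averaged with equal weights (no weights are dictated by
the data).

## Budget, calibration and projection

Gross production integrates G_net over valid cells.  Export is a perimeter
lump sum: 65 kg m^-1 yr^-1 along 4395 m of reef crest (285,675 kg/yr).
Available sediment volume is (gross - export) / rho with bulk density
rho = 1300 kg m^-3 — the density of loose biogenic carbonate sand/rubble, a
reconstructed default exposed in every config and report.  The closure
identity volume * rho = gross - export holds exactly, and negative volumes
(erosive budgets) are reported, never clamped.

Because the rate-law coefficient is a reconstruction, the pipeline
calibrates it: k is rescaled (one linear solve — gross production is
proportional to k) so the start-year available volume equals a configured
contemporary target, 569 m^3/yr by default.  The projection then holds the
community (A_c) and rugosity fixed, recomputes G_i per decade from the
trajectory, fits an OLS line to the decadal volumes, and reports the zero
crossing both from the fitted line (default) and from the endpoints alone —
the two extrapolations genuinely differ when the series curves, and both
are always reported.

With default settings the projected volume falls from 569 to ~170 m^3/yr by
2100 (~70% reduction), the linear fit has R^2 ~0.98, and the extrapolated
erosive year lands around 2150.

## Census validation

ReefBudget-style transects: ordered (taxon, surface length) segments, a
conforming tape length d1 and planar length d2, site rugosity d1/d2.
Production per planar m^2 is sum(length_i * K_c_i)/d2 over calcifier
segments — surface lengths in the numerator, so rugosity enters through
d1 > d2.  (For a fully conforming tape this is algebraically identical to
planar covers times a d1/d2 factor.)  Sand, rubble, turf, dead coral, soft
coral and macroalgae contribute zero; there is no bioerosion debit.  Coral
growth forms map onto the two coral rate classes (branching -> 10;
encrusting/massive/platy -> 3).

Synthetic transects are drawn on slope cells stratified across the 3.5-10.5 m
band (field transects sit near 10 m), with segment lengths following the
cell's covers under 5% multiplicative measurement noise.  The comparison
feeds the rate law with the *same* covers the transects sample, so the R^2
(~0.9 across seeds) measures agreement between the two estimators rather
than habitat-map error.  Note the resulting census values (~3-5.5 kg CaCO3
m^-2 yr^-1 on these high-cover slope sites) sit at and above the top of the
range field surveys report; published transect tables are not arithmetically
consistent with cover-times-rate accounting, so they serve as a plausibility
band only.

## Island reconstruction

The synthetic island is a paraboloid dome (radius 370 m, height 8.55 m —
area ~0.43 km^2, volume pi R^2 h / 2 ~ 1.84e6 m^3) modulated by north-south
shingle ridges whose term is odd in the east-west offset, so the continuum
volume is exactly the dome volume; the grid sum converges to it within well
under 1% at 4 m cells.  Island volume sums max(z - base, 0) * cell area, and
the historic accretion rate divides volume by the age of initial deposition
(default 3200 years), giving ~572-575 m^3/yr — the same order as the
contemporary budget, which is the comparison the method is designed to make.

## Numerical and testing choices

- Nodata is NaN everywhere and propagates; edge cells with incomplete
  stencils/windows are nodata by contract.
- Rasters are written as Esri ASCII grids with a JSON sidecar: plain text,
  readable by standard GIS tools, no binary dependencies.
- All generators take explicit integer seeds (no global random state);
  identical seeds give bit-identical outputs, and the pipeline manifest is
  byte-identical across repeated runs.
- Default problem sizes (100x100 platform, 200x200 island, 11 decadal steps,
  100-replicate recovery ensembles) keep a full pipeline run around 0.1 s
  and the entire test suite a few seconds, while being large enough for the
  statistical checks to be stable.
- The statistical map-accuracy check uses a small fixed seed ensemble: the
  generator is tuned to operate near R^2 ~0.82, so single seeds scatter
  roughly 0.79-0.84 and the ensemble mean is the stable quantity.

## Known limitations

- The rate-law coefficients are reconstructions; absolute G_i levels are
  only meaningful after calibration against a budget constraint.
- Calcification and dissolution cannot be partitioned within a zone; the
  flat's G_i is a net quantity.
- Export flux, community composition and rugosity are held constant across
  the projection; no bleaching, reassembly, sea-level or sediment-transport
  dynamics.
- The linear cover model cannot express mid-depth optima except through the
  slope/rugosity covariates; real zonation is sharper than the synthetic
  scenes.
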