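# reefcarb

Deterministic modelling of reef-platform carbonate production and the
sediment budget that sustains a reef island — past, present and through the
21st century under ocean acidification.

Reef islands are built entirely from carbonate sediment produced by the
surrounding reef ("the biological sediment factory").  Whether an island
keeps growing therefore reduces to a budget question: how much carbonate the
platform's benthic communities precipitate each year, how much leaves the
system, and how both respond as seawater aragonite saturation declines.
`reefcarb` implements that budget end to end for geomorphologists and reef
scientists, exercised entirely on seeded synthetic scenes with known ground
truth so every stage is testable without any field data.

## The model

Net community calcification is computed per raster cell as

```
G_net = A_c · k'_r · G_i(Ω, T)        [kg CaCO₃ m⁻² yr⁻¹]
```

- `G_i = k·sign(Ω−1)·|Ω−1|^n` — inorganic aragonite precipitation as a
  function of saturation state Ω, averaged over a tidal cycle per season and
  per zone (the ponded reef flat sees much larger Ω excursions than the
  slope);
- `A_c = Σᵢ Pᵢ·K_cᵢ / K_max` — the cover-weighted calcification fraction of
  the community, from covers Pᵢ of four producers (branching coral,
  non-branching coral, crustose coralline algae, *Halimeda*; Pacific rates
  K_c = 10, 3, 1.49, 1.80 kg CaCO₃ m⁻² yr⁻¹) mapped by linear regression on
  reflectance, depth, slope and rugosity;
- `k'_r` — terrain rugosity, the 3-D/planar surface-area ratio from the DEM.

Platform totals minus perimeter export (65 kg m⁻¹ yr⁻¹ × 4395 m), divided
by a bulk density of 1300 kg m⁻³, give the annual sediment volume available
for island building.  That volume is compared against the island's historic
accretion rate (DEM volume / radiocarbon age) and projected to 2100 on a
decadal Ω trajectory declining to a mean of 2.13 (diurnal range 0.85–3.95),
with the community held fixed.  See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

Running `python examples/05_projection.py` (full pipeline, seed 1) prints:

```
available volume 2000: 569 m^3/yr (calibrated)
available volume 2100: 174 m^3/yr (70% reduction)
trend: -3.94 m^3/yr per year, R^2 0.982
erosive state reached (trend extrapolation): 2152
erosive state reached (endpoint extrapolation): 2144
```

Reading: the rate coefficient is calibrated so the year-2000 budget matches
the contemporary estimate of 569 m³ of sediment per year; under the
acidification trajectory the same community produces only ~174 m³/yr by
2100.  Although Ω declines exponentially, the volume series is nearly
linear (R² 0.98) because the milder slope-zone chemistry damps the reef
flat's nonlinearity; extrapolating the fitted line puts the switch to a net
erosive state — the island losing volume — around the middle of the next
century.  The other scripts in `examples/` demonstrate scene generation,
terrain covariates, habitat mapping (mean map R² ≈ 0.8), the per-pixel
budget, and census validation (census vs rate law R² ≈ 0.9).

A thin CLI wraps the same pipeline:

```
reefcarb init-config config.yaml
reefcarb run-all --config config.yaml --seed 1 --outdir out/
```

writing every intermediate (ASCII-grid rasters, CSVs, model JSON) plus a
manifest of headline numbers.

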