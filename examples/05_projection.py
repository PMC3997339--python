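"""Project available sediment volume to 2100 under ocean acidification.

Reef-flat aragonite saturation declines (accelerating) to a mean of 2.13 by
2100 with diurnal limits 3.95/0.85; the slope declines less.  The benthic
community is held fixed, so only the chemistry term G_i changes.  A straight
line fitted to the decadal volumes is extrapolated to its zero crossing —
the year the sediment budget turns erosive.
"""

from reefcarb.pipeline import RunConfig, run_all

manifest = run_all(RunConfig(seed=1))

v0 = manifest["start_year_available_volume_m3_yr"]
v1 = manifest["end_year_available_volume_m3_yr"]
print(f"available volume 2000: {v0:.0f} m^3/yr (calibrated)")
print(f"available volume 2100: {v1:.0f} m^3/yr "
      f"({manifest['percent_reduction']:.0f}% reduction)")
print(f"trend: {manifest['trend_slope_m3_yr_per_yr']:.2f} m^3/yr per year, "
      f"R^2 {manifest['trend_r_squared']:.3f}")
print(f"erosive state reached (trend extrapolation): "
      f"{manifest['erosive_year_trend']:.0f}")
print(f"erosive state reached (endpoint extrapolation): "
      f"{manifest['erosive_year_endpoints']:.0f}")
# Despite the accelerating Omega decline, the volume series is close to
# linear (R^2 > 0.95): the milder slope-zone chemistry damps the ponded
# reef flat's nonlinearity.
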