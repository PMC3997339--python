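"""Fit the cover regression from ground samples and map the producers.

Fifty sample points (emulating boat-based video drops) give one OLS equation
per producer; the fitted coefficients applied to the covariate rasters
predict cover across the whole platform, and 218 independent points assess
map accuracy as R^2 of predicted vs observed cover.
"""

from reefcarb import GridSpec, evaluate_fit, fit_cover_model, generate_scene, predict_cover
from reefcarb.synthetic import sample_cover_points

scene = generate_scene(GridSpec(100, 100, 12.0), seed=0)

fit_samples = sample_cover_points(scene, 50, seed=1, cover_noise_sd=0.05)
model = fit_cover_model(fit_samples)
predicted = predict_cover(model, scene.covariate_rasters())

validation = sample_cover_points(scene, 218, seed=2, cover_noise_sd=0.05)
per_producer, mean_r2 = evaluate_fit(predicted, validation)

for producer in model.producers:
    beta_depth = model.coefficients[producer][3]
    print(f"{producer:<20s} R^2 {per_producer[producer]:.2f}   "
          f"depth coefficient {beta_depth:+.4f} per m")
print(f"mean map R^2: {mean_r2:.2f}")
# R^2 near 0.8 means the five physical covariates explain most of the
# spatial cover variation; the residual is observation noise and patchiness.
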