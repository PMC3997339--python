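"""Spatially explicit regression mapping of carbonate-producer cover.

Each producer's cover fraction is modelled as an ordinary-least-squares
linear function of five physical covariates (two reflectance bands, depth,
slope, rugosity).  Fitted coefficients are combined with the covariate
rasters to predict cover across the whole platform; raw predictions are
clipped to [0, 1] and, where the clipped covers of a cell sum to more than 1,
rescaled proportionally to sum to exactly 1.  Map accuracy is evaluated as
the coefficient of determination of predicted versus observed cover at
reference points (nearest-cell lookup, no interpolation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .raster import Raster, require_coregistered

__all__ = [
    "COVARIATES",
    "CoverSample",
    "CoverModel",
    "fit_cover_model",
    "predict_cover",
    "evaluate_fit",
]

#: covariate names, fixed order (design matrix is [1] + this order)
COVARIATES = ("reflectance_b1", "reflectance_b2", "depth", "slope", "rugosity")


@dataclass
class CoverSample:
    """Observed covers and covariates at one ground-reference location."""

    x: float
    y: float
    covers: Mapping[str, float]
    covariates: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.covers.items():
            if not -1e-9 <= value <= 1 + 1e-9:
                raise ValueError(f"cover '{name}'={value} outside [0, 1]")
        for name in COVARIATES:
            if name not in self.covariates or not np.isfinite(self.covariates[name]):
                raise ValueError(f"covariate '{name}' missing or non-finite")


@dataclass
class CoverModel:
    """OLS coefficients and diagnostics, one equation per producer."""

    producers: tuple[str, ...]
    coefficients: dict[str, np.ndarray]  # intercept first, then COVARIATES order
    r_squared: dict[str, float]
    residual_variance: dict[str, float]
    conf_int_95: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_names: tuple[str, ...] = COVARIATES

    def to_json(self, path: str | Path) -> None:
        payload = {
            "covariates": list(self.covariate_names),
            "producers": {
                p: {
                    "coefficients": self.coefficients[p].tolist(),
                    "r_squared": self.r_squared[p],
                    "residual_variance": self.residual_variance[p],
                }
                for p in self.producers
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoverModel":
        payload = json.loads(Path(path).read_text())
        producers = tuple(sorted(payload["producers"]))
        return cls(
            producers=producers,
            coefficients={
                p: np.asarray(payload["producers"][p]["coefficients"])
                for p in producers
            },
            r_squared={p: payload["producers"][p]["r_squared"] for p in producers},
            residual_variance={
                p: payload["producers"][p]["residual_variance"] for p in producers
            },
            covariate_names=tuple(payload["covariates"]),
        )


def _design_matrix(samples: Sequence[CoverSample]) -> np.ndarray:
    rows = [[1.0] + [s.covariates[c] for c in COVARIATES] for s in samples]
    return np.asarray(rows, dtype=float)


def _name_collinear_columns(x: np.ndarray) -> list[str]:
    """Column names implicated in a rank deficiency (QR with pivoting)."""
    from scipy.linalg import qr

    names = ("intercept",) + COVARIATES
    _, r, piv = qr(x, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def fit_cover_model(samples: Sequence[CoverSample]) -> CoverModel:
    """Fit one OLS cover equation per producer from ground samples."""
    if not samples:
        raise ValueError("no samples supplied")
    producers = tuple(sorted(samples[0].covers))
    n_params = len(COVARIATES) + 1
    if len(samples) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} samples for {n_params} parameters, "
            f"got {len(samples)}"
        )
    x = _design_matrix(samples)
    if np.linalg.matrix_rank(x) < n_params:
        cols = _name_collinear_columns(x)
        raise ValueError(f"design matrix is rank deficient; collinear: {cols}")
    coefficients, r2, resid_var, conf = {}, {}, {}, {}
    for producer in producers:
        y = np.array([s.covers[producer] for s in samples], dtype=float)
        res = sm.OLS(y, x).fit()
        coefficients[producer] = np.asarray(res.params)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2[producer] = 1.0 if tss == 0.0 else float(res.rsquared)
        resid_var[producer] = float(res.mse_resid) if res.df_resid > 0 else 0.0
        conf[producer] = np.asarray(res.conf_int(alpha=0.05))
    return CoverModel(producers, coefficients, r2, resid_var, conf)


def predict_cover(
    model: CoverModel, covariate_rasters: Mapping[str, Raster]
) -> dict[str, Raster]:
    """Predict cover rasters for every producer in the model.

    Per-cell linear prediction, clipped to [0, 1]; cells where the clipped
    covers sum to more than 1 are rescaled proportionally to sum to 1.
    Nodata in any covariate propagates.
    """
    missing = [c for c in COVARIATES if c not in covariate_rasters]
    if missing:
        raise ValueError(f"missing covariate raster(s): {missing}")
    grid = require_coregistered(**{c: covariate_rasters[c] for c in COVARIATES})
    stack = np.stack([covariate_rasters[c].values for c in COVARIATES])
    raw = {}
    for producer in model.producers:
        beta = model.coefficients[producer]
        pred = beta[0] + np.tensordot(beta[1:], stack, axes=1)
        raw[producer] = np.clip(pred, 0.0, 1.0)
    total = sum(raw.values())
    with np.errstate(invalid="ignore"):
        scale = np.where(total > 1.0, total, 1.0)
    return {p: Raster(raw[p] / scale, grid) for p in model.producers}


def evaluate_fit(
    predicted: Mapping[str, Raster], reference: Sequence[CoverSample]
) -> tuple[dict[str, float], float]:
    """Coefficient of determination of predicted vs observed covers.

    Returns (per-producer R^2, unweighted mean).  R^2 is computed against the
    observation mean: identical predictions give 1, predicting the mean gives
    0, worse-than-mean predictions go negative.
    """
    if len(reference) < 3:
        raise ValueError("need at least 3 reference points")
    r2: dict[str, float] = {}
    for producer, raster in predicted.items():
        obs, pred = [], []
        for sample in reference:
            value = raster.value_at(sample.x, sample.y)
            if not np.isfinite(value):
                raise ValueError(
                    f"reference point ({sample.x}, {sample.y}) falls on nodata"
                )
            obs.append(sample.covers[producer])
            pred.append(value)
        obs_arr, pred_arr = np.asarray(obs), np.asarray(pred)
        ss_res = float(np.sum((obs_arr - pred_arr) ** 2))
        ss_tot = float(np.sum((obs_arr - obs_arr.mean()) ** 2))
        r2[producer] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return r2, float(np.mean(list(r2.values())))
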