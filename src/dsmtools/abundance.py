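"""Gridded prediction, total abundance, and uncertainty propagation.

Predictions are made on a regular grid (4 km cells by default); the total
is the plain sum of per-cell abundances.  Uncertainty combines two
independent sources in quadrature on the CV scale,

    CV_total^2 = CV_det^2 + CV_gam^2,

where CV_det is the delta-method CV of the average detection probability
(detection is fitted to pooled data, the GAM per species, so independence
is reasonable) and CV_gam the delta-method CV of the GAM's total predicted
abundance through the posterior coefficient covariance.  The interval is
the standard lognormal distance-sampling CI:

    C = exp( z_{0.975} sqrt(ln(1 + CV_total^2)) ),   [N/C, N*C].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dsm import DSMFit
from .rasters import RasterStack
from .survey_io import annotate

__all__ = [
    "PredictionGrid",
    "AbundanceEstimate",
    "build_grid",
    "predict_total",
    "gam_cv",
    "total_cv",
    "lognormal_ci",
    "estimate_abundance",
]

log = logging.getLogger(__name__)


def build_grid(
    bounds: tuple[float, float, float, float],
    stack: RasterStack,
    resolution_km: float = 4.0,
    covariates: list[str] | None = None,
    date=None,
) -> pd.DataFrame:
    """Square prediction cells tiling ``bounds = (xmin, ymin, xmax, ymax)``
    (projected metres), annotated with raster covariates at cell centres.

    Edge cells that the extent does not fully contain are clipped: kept,
    with their area reduced to the part inside the bounds.  Cells with any
    missing covariate are excluded (counted in the log).
    """
    xmin, ymin, xmax, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty prediction region")
    res_m = resolution_km * 1000.0
    nx = int(np.ceil((xmax - xmin) / res_m))
    ny = int(np.ceil((ymax - ymin) / res_m))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x0 = xmin + ix.ravel() * res_m
    y0 = ymin + iy.ravel() * res_m
    wx = np.minimum(x0 + res_m, xmax) - x0
    wy = np.minimum(y0 + res_m, ymax) - y0
    grid = pd.DataFrame(
        {
            "x": x0 + wx / 2.0,
            "y": y0 + wy / 2.0,
            "area_km2": (wx / 1000.0) * (wy / 1000.0),
            "date": date,
        }
    )
    grid = annotate(grid, stack, covariates)
    n_missing = int(grid["covariate_missing"].sum())
    if n_missing:
        log.warning("build_grid: %d of %d cells dropped for missing covariates", n_missing, len(grid))
    grid = grid.loc[~grid["covariate_missing"]].drop(columns="covariate_missing")
    return grid.reset_index(drop=True)


def predict_total(fit: DSMFit, grid: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """(N_hat, per-cell table): N_hat_c = A_c exp(eta_c), summed without
    renormalization.  Cells beyond any fitted covariate range are flagged
    ``extrapolated`` (they still contribute to the total)."""
    needed = {c for sm in fit.gam.smooths for c in sm.covariates}
    missing = sorted(needed - set(grid.columns))
    if missing:
        raise ValueError(f"prediction grid lacks covariates {missing}")
    out = grid.copy()
    nhat = fit.gam.predict(out, offset=np.log(out["area_km2"].to_numpy()))
    out["Nhat"] = nhat
    extrap = np.zeros(len(out), dtype=bool)
    for cov, (lo, hi) in fit.gam.fit_ranges.items():
        if cov in out.columns:
            v = out[cov].to_numpy(dtype=float)
            extrap |= (v < lo) | (v > hi)
    out["extrapolated"] = extrap
    if extrap.any():
        log.info("predict_total: %d of %d cells extrapolate beyond fitted covariate ranges",
                 int(extrap.sum()), len(out))
    return float(nhat.sum()), out


def gam_cv(fit: DSMFit, grid: pd.DataFrame) -> float:
    """Delta-method CV of total predicted abundance through V_beta:
    var(N) = a' V a with a = sum_c N_c x_c (log link)."""
    N, cells = predict_total(fit, grid)
    X = fit.gam.design_matrix(cells)
    a = X.T @ cells["Nhat"].to_numpy()
    V = fit.gam.V_beta
    if not np.all(np.isfinite(V)):
        raise ValueError("coefficient covariance is not finite")
    var = float(a @ V @ a)
    if var < 0:
        raise ValueError("negative delta-method variance (singular V_beta?)")
    return float(np.sqrt(var) / N)


def total_cv(cv_det: float, cv_gam: float) -> float:
    """Independent CV components combined in quadrature."""
    if cv_det < 0 or cv_gam < 0:
        raise ValueError("CVs must be nonnegative")
    return float(np.sqrt(cv_det**2 + cv_gam**2))


def lognormal_ci(n_hat: float, cv: float, level: float = 0.95) -> tuple[float, float]:
    """Lognormal confidence interval [N/C, N*C],
    C = exp(z_{(1+level)/2} sqrt(ln(1 + cv^2)))."""
    if n_hat <= 0:
        raise ValueError("N_hat must be positive")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    C = float(np.exp(z * np.sqrt(np.log1p(cv**2))))
    return n_hat / C, n_hat * C


@dataclass
class AbundanceEstimate:
    """Total abundance over a prediction grid with propagated uncertainty."""

    species: str | None
    n_hat: float
    cv_gam: float
    cv_det: float
    cv_total: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_cells: int = 0
    n_extrapolated: int = 0

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "N_hat": float(self.n_hat),
            "cv_gam": float(self.cv_gam),
            "cv_det": float(self.cv_det),
            "cv_total": float(self.cv_total),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "confidence_level": float(self.level),
            "n_cells": int(self.n_cells),
            "n_extrapolated": int(self.n_extrapolated),
        }


def estimate_abundance(
    fit: DSMFit, grid: pd.DataFrame, cv_det: float, level: float = 0.95
) -> tuple[AbundanceEstimate, pd.DataFrame]:
    """Full abundance summary for one species over a prediction grid."""
    n_hat, cells = predict_total(fit, grid)
    cvg = gam_cv(fit, grid)
    fit.cv_gam = cvg
    cvt = total_cv(cv_det, cvg)
    lo, hi = lognormal_ci(n_hat, cvt, level)
    est = AbundanceEstimate(
        species=fit.spec.species, n_hat=n_hat, cv_gam=cvg, cv_det=cv_det,
        cv_total=cvt, ci_low=lo, ci_high=hi, level=level,
        n_cells=len(cells), n_extrapolated=int(cells["extrapolated"].sum()),
    )
    return est, cells
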