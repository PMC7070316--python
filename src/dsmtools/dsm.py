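"""Second stage of the density surface model: segment responses and the
spatial GAM.

Per-segment abundance is the Horvitz-Thompson estimate
``n_hat_j = sum_{i in j} s_i / p_i`` (individuals) or ``sum 1/p_i``
(clusters), with the searched area ``A_j = 2 w l_j`` entering the model as
a log offset:

    E[n_hat_j] = A_j exp( beta0 + sum_k f_k(z_jk) ).

Species enter only here — the detection function is fitted to pooled
distances — and unidentified clusters are excluded from species-level
responses.  Backward term selection removes the largest-p smooth above the
significance threshold, refits, and repeats until every remaining term is
significant, returning an auditable removal trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import GAMFit, Smooth1D, TensorSmooth2D, fit_penalized_gam

__all__ = [
    "DSMModelSpec",
    "DSMFit",
    "segment_abundance",
    "build_response_table",
    "fit_gam",
    "backward_select",
    "compare_models",
    "qq_diagnostics",
]

log = logging.getLogger(__name__)

XY_TERM = "xy"  # joint latitude/longitude smooth: always one bivariate term

DEFAULT_K_1D = 10
DEFAULT_K_XY = 25
MIN_SEGMENTS = 50


def segment_abundance(cluster_sizes, p_i, unit: str = "individuals") -> float:
    """Horvitz-Thompson estimate for one segment; 0 for an empty segment."""
    s = np.asarray(cluster_sizes, dtype=float)
    p = np.asarray(p_i, dtype=float)
    if s.size == 0:
        return 0.0
    if np.any(p <= 0):
        raise ValueError("detection probabilities must be positive")
    if np.any(p > 1):
        raise ValueError("detection probabilities must be <= 1")
    if unit == "individuals":
        return float(np.sum(s / p))
    if unit == "clusters":
        return float(np.sum(1.0 / p))
    raise ValueError(f"unit must be 'individuals' or 'clusters', got {unit!r}")


def build_response_table(
    segments: pd.DataFrame,
    sightings: pd.DataFrame,
    w: float,
    species: str | None = None,
    unit: str = "individuals",
    p_col: str = "p_i",
) -> pd.DataFrame:
    """One row per segment with the HT response and searched area.

    ``sightings`` must carry ``segment_id`` (see
    :func:`dsmtools.survey_io.assign_sightings_to_segments`) and fitted
    ``p_i``.  ``species=None`` pools all identified and unidentified
    clusters; a species name restricts to that species.
    """
    sel = sightings
    if species is not None:
        sel = sightings.loc[sightings["species"] == species]
    nhat = {
        seg_id: segment_abundance(grp["cluster_size"], grp[p_col], unit)
        for seg_id, grp in sel.groupby("segment_id")
    }
    out = segments.copy()
    out["nhat"] = out["segment_id"].map(nhat).fillna(0.0)
    out["count"] = (
        out["segment_id"].map(sel.groupby("segment_id").size()).fillna(0).astype(int)
    )
    out["area_km2"] = 2.0 * (w / 1000.0) * out["length_km"]
    return out


@dataclass
class DSMModelSpec:
    """What to fit: species, response family, candidate smooth terms.

    ``terms`` uses covariate names plus the special name ``"xy"`` for the
    joint spatial smooth.  ``alpha`` is the backward-selection threshold
    (0.05 default; the striped-dolphin analysis uses 0.1).
    """

    species: str | None = None
    family: str = "tweedie"
    terms: tuple = ("xy", "depth", "slope", "dfc", "df200", "sst", "chl")
    alpha: float = 0.05
    k: dict = field(default_factory=dict)
    unit: str = "individuals"
    q: float | None = None
    theta: float | None = None
    q_grid: tuple | None = None  # coarser Tweedie-power grid for small runs

    def make_smooths(self) -> list:
        out = []
        for t in self.terms:
            if t == XY_TERM:
                out.append(TensorSmooth2D(("x", "y"), k=self.k.get(t, DEFAULT_K_XY)))
            else:
                out.append(Smooth1D(t, k=self.k.get(t, DEFAULT_K_1D)))
        return out

    def drop_term(self, label: str) -> "DSMModelSpec":
        keep = tuple(
            t for t in self.terms
            if (f"s(x,y)" if t == XY_TERM else f"s({t})") != label
        )
        return DSMModelSpec(
            species=self.species, family=self.family, terms=keep, alpha=self.alpha,
            k=self.k, unit=self.unit, q=self.q, theta=self.theta, q_grid=self.q_grid,
        )


@dataclass
class DSMFit:
    """A fitted density surface model for one species."""

    spec: DSMModelSpec
    gam: GAMFit
    n_segments: int
    n_dropped_missing: int
    removal_trail: list = field(default_factory=list)
    cv_gam: float | None = None  # filled by the abundance stage

    @property
    def deviance_explained(self) -> float:
        return self.gam.deviance_explained

    @property
    def term_pvalues(self) -> dict:
        return self.gam.term_pvalues

    def to_dict(self) -> dict:
        g = self.gam
        return {
            "species": self.spec.species,
            "family": g.family,
            "tweedie_power": g.q,
            "nb_theta": g.theta,
            "terms": g.term_labels,
            "edf": {k: float(v) for k, v in g.edf.items()},
            "p_values": {k: float(v) for k, v in g.term_pvalues.items()},
            "deviance_explained": float(g.deviance_explained),
            "REML": float(g.reml),
            "AIC": float(g.aic),
            "n_segments": int(self.n_segments),
            "n_dropped_missing": int(self.n_dropped_missing),
            "removal_trail": self.removal_trail,
        }


def _prepare(responses: pd.DataFrame, spec: DSMModelSpec) -> pd.DataFrame:
    needed = [c for t in spec.terms for c in (("x", "y") if t == XY_TERM else (t,))]
    missing_cols = [c for c in needed if c not in responses.columns]
    if missing_cols:
        raise ValueError(f"response table lacks covariates {missing_cols}")
    ok = responses[needed].notna().all(axis=1) if needed else pd.Series(True, index=responses.index)
    dropped = int((~ok).sum())
    if dropped:
        log.info("fit_gam: dropped %d segments with missing covariates", dropped)
    return responses.loc[ok].reset_index(drop=True), dropped


def fit_gam(responses: pd.DataFrame, spec: DSMModelSpec) -> DSMFit:
    """Fit the spatial GAM for one species' response table."""
    data, dropped = _prepare(responses, spec)
    if len(data) < MIN_SEGMENTS:
        raise ValueError(f"need >= {MIN_SEGMENTS} segments with complete covariates, have {len(data)}")
    gam = fit_penalized_gam(
        data,
        "nhat",
        spec.make_smooths(),
        family=spec.family,
        offset=np.log(data["area_km2"].to_numpy()),
        q=spec.q,
        theta=spec.theta,
        q_grid=None if spec.q_grid is None else np.asarray(spec.q_grid),
    )
    return DSMFit(spec=spec, gam=gam, n_segments=len(data), n_dropped_missing=dropped)


def backward_select(responses: pd.DataFrame, spec: DSMModelSpec) -> DSMFit:
    """Iteratively drop the largest-p term with p > alpha and refit until all
    remaining terms are significant.  The removal trail is kept on the fit."""
    trail = []
    fit = fit_gam(responses, spec)
    while fit.gam.term_pvalues:
        label, p = max(fit.gam.term_pvalues.items(), key=lambda kv: kv[1])
        if p <= spec.alpha:
            break
        trail.append({"removed": label, "p_value": float(p)})
        spec = spec.drop_term(label)
        if not spec.terms:
            log.warning("backward selection removed every term; intercept-only model")
        fit = fit_gam(responses, spec)
    fit.removal_trail = trail
    return fit


def compare_models(fits: list[DSMFit]) -> pd.DataFrame:
    """Side-by-side comparison table; flags the best fit per criterion."""
    if not fits:
        raise ValueError("no fits to compare")
    y0 = fits[0].gam.y
    for f in fits[1:]:
        if len(f.gam.y) != len(y0) or not np.allclose(f.gam.y, y0):
            raise ValueError("fits are not on identical response data")
    rows = []
    for f in fits:
        g = f.gam
        rows.append(
            {
                "species": f.spec.species,
                "family": g.family + (f" (q={g.q:.2f})" if g.q else f" (theta={g.theta:.2f})" if g.theta else ""),
                "terms": " + ".join(g.term_labels) or "(intercept)",
                "AIC": g.aic,
                "REML": g.reml,
                "deviance_explained_pct": 100.0 * g.deviance_explained,
                "cv_gam": f.cv_gam,
            }
        )
    table = pd.DataFrame(rows)
    table["best_AIC"] = table["AIC"] == table["AIC"].min()
    table["best_REML"] = table["REML"] == table["REML"].min()
    table["best_deviance"] = table["deviance_explained_pct"] == table["deviance_explained_pct"].max()
    return table


def qq_diagnostics(fit: DSMFit) -> pd.DataFrame:
    """Ordered deviance residuals against normal reference quantiles."""
    r = np.sort(fit.gam.quantile_residuals())
    n = len(r)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n, scale=max(np.std(r), 1e-12))
    return pd.DataFrame({"theoretical": theo, "observed": r})
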