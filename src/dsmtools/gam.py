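"""Penalized-regression GAM engine (log link, Tweedie / negative binomial).

Fits models of the form

    E[y_j] = A_j * exp( beta0 + sum_k f_k(z_jk) ),   Var[y_j] = phi * V(mu_j)

by penalized iteratively reweighted least squares.  Smooths are P-splines
(uniform cubic B-spline bases with a second-order difference penalty); the
bivariate spatial term is a tensor product of two marginal bases with an
isotropic Kronecker-sum penalty.  Every smooth carries a sum-to-zero
constraint absorbed by reparameterization so the intercept is identifiable.

Smoothing parameters are chosen by minimizing the restricted marginal
likelihood (REML) of the working Gaussian model at the converged PIRLS
weights, with the dispersion profiled by the Pearson estimator — the
"performance iteration" REML of penalized GLMs.  Family machinery
(variance functions, deviance, and the Tweedie series log-likelihood) comes
from statsmodels; the Tweedie power is estimated by profiling that
likelihood over a grid in (1.1, 1.9), and the negative-binomial size theta
by maximum likelihood within the fit loop.

The posterior (Bayesian) covariance ``V_beta = phi * (X'WX + S_lambda)^-1``
drives both the approximate Wald tests on smooth terms and the delta-method
variance of predicted abundance downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, linalg, optimize, stats
from statsmodels.genmod import families

__all__ = ["Smooth1D", "TensorSmooth2D", "GAMFit", "fit_penalized_gam"]

log = logging.getLogger(__name__)

_MU_FLOOR = 1e-10


def _bspline_design(x: np.ndarray, lo: float, hi: float, k: int, degree: int = 3) -> np.ndarray:
    """Uniform (P-spline) B-spline design with k basis functions on [lo, hi]."""
    nseg = k - degree
    if nseg < 1:
        raise ValueError(f"basis dimension k={k} too small for degree {degree}")
    h = (hi - lo) / nseg
    # linspace pins the boundary knots to lo/hi exactly (no drift at 1 ulp)
    interior = np.linspace(lo, hi, nseg + 1)
    t = np.concatenate([lo - h * np.arange(degree, 0, -1), interior, hi + h * np.arange(1, degree + 1)])
    xc = np.clip(x, lo, hi)  # clamp: outside-range points flagged upstream
    return interpolate.BSpline.design_matrix(xc, t, degree).toarray()


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


class Smooth1D:
    """One-dimensional penalized spline term f(z)."""

    def __init__(self, name: str, k: int = 10, degree: int = 3, penalty_order: int = 2):
        self.name = name
        self.label = f"s({name})"
        self.k = k
        self.degree = degree
        self.penalty_order = penalty_order
        self._fitted = False

    @property
    def covariates(self) -> tuple[str, ...]:
        return (self.name,)

    def setup(self, data) -> None:
        x = np.asarray(data[self.name], dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError(f"covariate {self.name!r} is constant; cannot smooth")
        self.lo, self.hi = lo, hi
        X = _bspline_design(x, lo, hi, self.k, self.degree)
        S = _diff_penalty(self.k, self.penalty_order)
        c = X.mean(axis=0)
        self.Z = linalg.null_space(c[None, :])        # (k, k-1) sum-to-zero
        self.S = self.Z.T @ S @ self.Z
        self.rank = np.linalg.matrix_rank(self.S)
        self.dim = self.Z.shape[1]
        self._fitted = True

    def design(self, data) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("setup() not called")
        x = np.asarray(data[self.name], dtype=float)
        return _bspline_design(x, self.lo, self.hi, self.k, self.degree) @ self.Z


class TensorSmooth2D:
    """Tensor-product smooth f(x, y) for the joint spatial term.

    Penalty is the isotropic Kronecker sum S_x (x) I + I (x) S_y with a
    single smoothing parameter, appropriate when both margins are in the
    same units (projected metres).
    """

    def __init__(self, names: tuple[str, str] = ("x", "y"), k: int = 25, degree: int = 3):
        self.names = tuple(names)
        self.label = f"s({','.join(self.names)})"
        self.k_marginal = max(int(round(np.sqrt(k))), degree + 1)
        self.k = self.k_marginal**2
        self.degree = degree
        self._fitted = False

    @property
    def name(self) -> str:
        return ",".join(self.names)

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.names

    def setup(self, data) -> None:
        self.ranges = {}
        km = self.k_marginal
        for nm in self.names:
            v = np.asarray(data[nm], dtype=float)
            lo, hi = float(np.min(v)), float(np.max(v))
            if hi <= lo:
                raise ValueError(f"covariate {nm!r} is constant; cannot smooth")
            self.ranges[nm] = (lo, hi)
        Sm = _diff_penalty(km, 2)
        I = np.eye(km)
        S = np.kron(Sm, I) + np.kron(I, Sm)
        X = self._raw_design(data)
        c = X.mean(axis=0)
        self.Z = linalg.null_space(c[None, :])
        self.S = self.Z.T @ S @ self.Z
        self.rank = np.linalg.matrix_rank(self.S)
        self.dim = self.Z.shape[1]
        self._fitted = True

    def _raw_design(self, data) -> np.ndarray:
        km = self.k_marginal
        mats = []
        for nm in self.names:
            lo, hi = self.ranges[nm]
            mats.append(_bspline_design(np.asarray(data[nm], dtype=float), lo, hi, km, self.degree))
        A, B = mats
        return np.einsum("ij,ik->ijk", A, B).reshape(len(A), km * km)

    def design(self, data) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("setup() not called")
        return self._raw_design(data) @ self.Z


# ---------------------------------------------------------------------------


def _make_family(family: str, q: float | None, theta: float | None):
    if family == "tweedie":
        return families.Tweedie(link=families.links.Log(), var_power=q, eql=False)
    if family == "nb":
        return families.NegativeBinomial(link=families.links.Log(), alpha=1.0 / theta)
    raise ValueError(f"unknown family {family!r} (expected 'tweedie' or 'nb')")


def _pirls(y, X, offset, fam, P, max_iter=100, tol=1e-9, eta0=None):
    """Penalized IRLS for a log-link model, with step halving on the
    penalized deviance; returns the converged state."""

    def _mu_of(eta):
        return np.maximum(np.exp(np.clip(eta + offset, -30, 30)), _MU_FLOOR)

    def _pdev(eta, beta):
        return fam.deviance(y, _mu_of(eta)) + (beta @ P @ beta if beta is not None else 0.0)

    if eta0 is not None:
        eta = eta0
    else:
        mu = np.maximum(y, 0) + np.mean(y) * 0.1 + 1e-6
        eta = np.log(mu) - offset
    beta = None
    pdev = np.inf
    for _ in range(max_iter):
        mu = _mu_of(eta)
        w = mu**2 / fam.variance(mu)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + P
        try:
            c, low = linalg.cho_factor(A)
            beta_new = linalg.cho_solve((c, low), XtW @ z)
        except linalg.LinAlgError as exc:
            raise RuntimeError("PIRLS normal equations singular (collinear terms?)") from exc
        eta_new = X @ beta_new
        pdev_new = _pdev(eta_new, beta_new)
        halvings = 0
        while (not np.isfinite(pdev_new) or pdev_new > pdev * (1 + 1e-10)) and beta is not None and halvings < 15:
            beta_new = 0.5 * (beta_new + beta)
            eta_new = X @ beta_new
            pdev_new = _pdev(eta_new, beta_new)
            halvings += 1
        if not np.isfinite(pdev_new):
            raise RuntimeError("PIRLS diverged (non-finite deviance)")
        # convergence on the linear predictor is robust where the penalized
        # deviance plateaus (very large lambda) and cancellation defeats a
        # deviance-change test
        eta_change = np.max(np.abs(eta_new - eta)) / (1.0 + np.max(np.abs(eta_new)))
        converged = (
            abs(pdev - pdev_new) < tol * (abs(pdev_new) + 0.1) or eta_change < 1e-7
        )
        beta, eta, pdev = beta_new, eta_new, pdev_new
        if converged:
            break
    else:
        log.debug("PIRLS hit iteration cap at penalized deviance %.6g", pdev)
    mu = _mu_of(eta)
    w = mu**2 / fam.variance(mu)
    z = eta + (y - mu) / mu
    return beta, eta, mu, w, z, fam.deviance(y, mu)


def _assemble(smooths, data):
    """Full design matrix [1 | X_1 | ...] and block bookkeeping."""
    n = len(data)
    cols = [np.ones((n, 1))]
    blocks = []
    start = 1
    for sm in smooths:
        Xs = sm.design(data)
        cols.append(Xs)
        blocks.append(slice(start, start + Xs.shape[1]))
        start += Xs.shape[1]
    return np.hstack(cols), blocks


def _penalty_matrix(p, smooths, blocks, lambdas):
    P = np.zeros((p, p))
    for sm, sl, lam in zip(smooths, blocks, lambdas):
        P[sl, sl] = lam * sm.S
    return P


def _reml_state(y, X, offset, fam, smooths, blocks, lambdas, eta0=None):
    """Fit at fixed lambdas and evaluate the working-model REML score."""
    p = X.shape[1]
    P = _penalty_matrix(p, smooths, blocks, lambdas)
    beta, eta, mu, w, z, dev = _pirls(y, X, offset, fam, P, eta0=eta0)
    XtWX = (X.T * w) @ X
    A = XtWX + P
    c, low = linalg.cho_factor(A)
    Ainv = linalg.cho_solve((c, low), np.eye(p))
    F = Ainv @ XtWX
    edf_total = float(np.trace(F))
    n = len(y)
    pearson = float(np.sum((y - mu) ** 2 / fam.variance(mu)))
    phi = pearson / max(n - edf_total, 1.0)
    Dp = float(np.sum(w * (z - eta) ** 2) + beta @ P @ beta)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    logdet_P = 0.0
    Mp = p
    for sm, lam in zip(smooths, lambdas):
        ev = np.linalg.eigvalsh(sm.S)
        pos = ev[ev > 1e-10 * ev.max()] if len(ev) and ev.max() > 0 else np.array([])
        logdet_P += sm.rank * np.log(lam) + float(np.sum(np.log(pos)))
        Mp -= sm.rank
    reml = (
        Dp / (2.0 * phi)
        + 0.5 * (logdet_A - logdet_P)
        + 0.5 * (n - Mp) * np.log(2.0 * np.pi * phi)
    )
    return {
        "beta": beta, "eta": eta, "mu": mu, "w": w, "dev": dev,
        "Ainv": Ainv, "F": F, "edf_total": edf_total, "phi": phi,
        "reml": float(reml), "lambdas": np.asarray(lambdas, dtype=float),
        "XtWX": XtWX,
    }


def _optimize_lambdas(y, X, offset, fam, smooths, blocks, rho0=None):
    m = len(smooths)
    if m == 0:
        return _reml_state(y, X, offset, fam, smooths, blocks, [])

    warm = {"eta": None}

    def objective(rho):
        # [-6, 12] spans edf ~ k-1 .. ~null for these problem scales; REML
        # is flat beyond, and unbounded rho lets the simplex wander there
        rho = np.clip(rho, -6.0, 12.0)
        try:
            st = _reml_state(y, X, offset, fam, smooths, blocks, np.exp(rho), eta0=warm["eta"])
        except (RuntimeError, linalg.LinAlgError):
            return 1e12
        warm["eta"] = st["eta"]
        return st["reml"]

    if rho0 is None:
        # coarse grid start (shared rho), then simplex refinement per term
        grid = np.linspace(-2, 10, 7)
        rho0 = min(([g] * m for g in grid), key=lambda r: objective(np.array(r)))
    res = optimize.minimize(
        objective, np.asarray(rho0, dtype=float), method="Nelder-Mead",
        options={"xatol": 0.1, "fatol": 1e-3, "maxiter": 80 * m},
    )
    rho = np.clip(res.x, -6.0, 12.0)
    state = _reml_state(y, X, offset, fam, smooths, blocks, np.exp(rho), eta0=warm["eta"])
    state["rho"] = rho
    return state


def _loglik(fam, y, mu, phi, family: str) -> float:
    if family == "tweedie":
        return float(np.sum(fam.loglike_obs(y, mu, scale=phi)))
    return float(np.sum(fam.loglike_obs(y, mu, scale=1.0)))


def _profile_theta(y, X, offset, smooths, blocks, theta0=1.0):
    """Alternate REML fits with NB theta updated by ML."""
    theta = theta0
    state = None
    rho = None
    for _ in range(4):
        fam = _make_family("nb", None, theta)
        state = _optimize_lambdas(y, X, offset, fam, smooths, blocks, rho0=rho)
        rho = state.get("rho")
        mu = state["mu"]

        def nll(log_theta):
            f = _make_family("nb", None, float(np.exp(log_theta)))
            return -float(np.sum(f.loglike_obs(y, mu, scale=1.0)))

        res = optimize.minimize_scalar(nll, bounds=(np.log(1e-2), np.log(1e4)), method="bounded")
        theta_new = float(np.exp(res.x))
        if abs(np.log(theta_new / theta)) < 1e-3:
            theta = theta_new
            break
        theta = theta_new
    fam = _make_family("nb", None, theta)
    state = _optimize_lambdas(y, X, offset, fam, smooths, blocks, rho0=rho)
    return state, fam, theta


@dataclass
class GAMFit:
    """Fitted penalized GAM: coefficients, covariance, and diagnostics."""

    family: str
    smooths: list
    blocks: list
    beta: np.ndarray
    V_beta: np.ndarray               # Bayesian posterior covariance
    phi: float
    q: float | None                  # Tweedie power
    theta: float | None              # NB size
    lambdas: np.ndarray
    edf: dict
    edf_total: float
    deviance: float
    null_deviance: float
    deviance_explained: float
    reml: float
    loglik: float
    aic: float
    term_pvalues: dict
    fitted: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    fit_ranges: dict = field(default_factory=dict)

    @property
    def term_labels(self) -> list[str]:
        return [sm.label for sm in self.smooths]

    def design_matrix(self, data) -> np.ndarray:
        X, _ = _assemble(self.smooths, data)
        return X

    def predict(self, data, offset: np.ndarray | None = None) -> np.ndarray:
        """Mean response at new covariates (offset on the log scale)."""
        X = self.design_matrix(data)
        eta = X @ self.beta
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)

    def quantile_residuals(self, seed: int = 0) -> np.ndarray:
        """Deviance residuals (signed square-root contributions)."""
        fam = _make_family(self.family, self.q, self.theta)
        return fam.resid_dev(self.y, self.fitted)


def fit_penalized_gam(
    data,
    response: str,
    smooths: list,
    family: str = "tweedie",
    offset: np.ndarray | None = None,
    q: float | None = None,
    theta: float | None = None,
    q_grid: np.ndarray | None = None,
) -> GAMFit:
    """Fit ``E[y] = exp(offset + beta0 + sum f_k)`` with REML-selected
    smoothing parameters.

    ``family='tweedie'`` profiles the variance power over ``q_grid``
    (default 1.2..1.8 by 0.1) unless ``q`` is given; ``family='nb'``
    estimates theta by ML unless fixed.  Raises on non-convergence or on a
    rank-deficient (collinear) design.
    """
    y = np.asarray(data[response], dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"too few rows to fit a GAM (n={n})")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    for sm in smooths:
        sm.setup(data)
    X, blocks = _assemble(smooths, data)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        labels = ", ".join(sm.label for sm in smooths)
        raise RuntimeError(f"design matrix rank-deficient; check terms: {labels}")

    if family == "tweedie":
        if q is not None:
            if not 1.0 < q < 2.0:
                raise ValueError("Tweedie power must lie in (1, 2)")
            fam = _make_family("tweedie", q, None)
            state = _optimize_lambdas(y, X, off, fam, smooths, blocks)
            q_hat, theta_hat = q, None
        else:
            grid = q_grid if q_grid is not None else np.arange(1.2, 1.81, 0.1)
            best = None
            rho = None  # warm-start lambda search across the power grid
            for qi in grid:
                fam_i = _make_family("tweedie", float(qi), None)
                st = _optimize_lambdas(y, X, off, fam_i, smooths, blocks, rho0=rho)
                rho = st.get("rho")
                ll = _loglik(fam_i, y, st["mu"], st["phi"], "tweedie")
                if best is None or ll > best[0]:
                    best = (ll, float(qi), st, fam_i)
            _, q_hat, state, fam = best
            theta_hat = None
    elif family == "nb":
        if theta is not None:
            fam = _make_family("nb", None, theta)
            state = _optimize_lambdas(y, X, off, fam, smooths, blocks)
            theta_hat = theta
        else:
            state, fam, theta_hat = _profile_theta(y, X, off, smooths, blocks)
        q_hat = None
    else:
        raise ValueError(f"unknown family {family!r}")

    # null (intercept + offset only) deviance for the same family
    null_state = _reml_state(y, np.ones((n, 1)), off, fam, [], [], [])
    null_dev = null_state["dev"]
    dev = state["dev"]
    dev_expl = float(1.0 - dev / null_dev) if null_dev > 0 else 0.0

    V_beta = state["phi"] * state["Ainv"]
    F = state["F"]
    edf = {}
    pvals = {}
    for sm, sl in zip(smooths, blocks):
        edf_j = float(np.trace(F[sl, sl]))
        edf[sm.label] = edf_j
        bj = state["beta"][sl]
        Vj = V_beta[sl, sl]
        try:
            stat = float(bj @ np.linalg.solve(Vj, bj))
        except np.linalg.LinAlgError:
            stat = float(bj @ np.linalg.pinv(Vj) @ bj)
        df = max(edf_j, 1e-3)
        pvals[sm.label] = float(stats.chi2.sf(stat, df))

    ll = _loglik(fam, y, state["mu"], state["phi"], family)
    aic = -2.0 * ll + 2.0 * (state["edf_total"] + 1.0)

    ranges = {}
    for sm in smooths:
        for cov in sm.covariates:
            v = np.asarray(data[cov], dtype=float)
            ranges[cov] = (float(v.min()), float(v.max()))

    return GAMFit(
        family=family, smooths=smooths, blocks=blocks, beta=state["beta"],
        V_beta=V_beta, phi=float(state["phi"]), q=q_hat, theta=theta_hat,
        lambdas=state["lambdas"], edf=edf, edf_total=float(state["edf_total"]),
        deviance=float(dev), null_deviance=float(null_dev),
        deviance_explained=dev_expl, reml=float(state["reml"]), loglik=ll,
        aic=float(aic), term_pvalues=pvals, fitted=state["mu"], y=y,
        offset=off, fit_ranges=ranges,
    )
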