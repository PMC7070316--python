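"""Detection-function shapes, likelihood fitting, and goodness of fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from dsmtools import detection as det
from dsmtools.synthetic import simulate_distances


# ---------------------------------------------------------------------------
# key function shapes


@pytest.mark.parametrize(
    "key, x, sigma, b, expected",
    [
        ("half_normal", 200.0, 200.0, None, np.exp(-0.5)),
        ("hazard_rate", 200.0, 200.0, 3.0, -np.expm1(-1.0)),
        ("hazard_rate", 250.0, 200.0, 2.5, 0.4358),  # 1 - exp(-(1.25)^-2.5)
    ],
)
def test_g_closed_forms(key, x, sigma, b, expected):
    assert det.g_value(key, x, sigma, b) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("key, b", [("half_normal", None), ("hazard_rate", 2.5), ("hazard_rate", 1.2)])
def test_g_monotone_and_anchored(key, b):
    x = np.linspace(0, 2000, 500)
    g = det.g_value(key, x, 300.0, b)
    assert g[0] == pytest.approx(1.0)
    assert np.all(np.diff(g) <= 1e-12)
    assert np.all((g > 0) & (g <= 1))


def test_g_invalid_parameters():
    with pytest.raises(ValueError):
        det.g_value("half_normal", -1.0, 200.0)
    with pytest.raises(ValueError):
        det.g_value("half_normal", 100.0, -5.0)
    with pytest.raises(ValueError):
        det.g_value("hazard_rate", 100.0, 200.0, None)
    with pytest.raises(ValueError):
        det.g_value("uniform", 100.0, 200.0)


def test_scale_sigma_log_linear():
    Z = np.array([[1.0, 0.0], [1.0, 1.0]])
    beta = np.array([np.log(200.0), np.log(2.0)])
    np.testing.assert_allclose(det.scale_sigma(Z, beta), [200.0, 400.0])
    with pytest.raises(ValueError):
        det.scale_sigma(Z, np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# effective strip width / detection probability


def test_effective_integral_half_normal_closed_form():
    # mu = sigma sqrt(pi/2) erf(w / (sigma sqrt 2))
    sigma, w = 200.0, 500.0
    expected = sigma * np.sqrt(np.pi / 2) * special.erf(w / (sigma * np.sqrt(2)))
    assert det.effective_integral("half_normal", sigma, w) == pytest.approx(expected, abs=1e-6)
    assert det.detection_probability("half_normal", sigma, w) == pytest.approx(0.4951, abs=2e-4)


def test_detection_probability_perfect_detection():
    assert det.detection_probability("half_normal", 1e9, 500.0) == pytest.approx(1.0, abs=1e-9)
    assert det.detection_probability("half_normal", 1e9, 250.0) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("key, sigma, b", [("half_normal", 150.0, None), ("hazard_rate", 200.0, 2.5), ("hazard_rate", 120.0, 1.5)])
def test_p_matches_simpson_oracle(key, sigma, b):
    """Internal quadrature agrees with a 10^4-panel Simpson rule to 1e-6."""
    w = 500.0
    xs = np.linspace(0, w, 10_001)
    simpson_p = integrate.simpson(det.g_value(key, xs, sigma, b), x=xs) / w
    assert det.detection_probability(key, sigma, w, b) == pytest.approx(simpson_p, abs=1e-6)
    # vectorized path used inside the likelihood
    mu = det._mu_vec(key, np.array([sigma]), w, b)
    assert mu[0] / w == pytest.approx(simpson_p, abs=1e-6)


# ---------------------------------------------------------------------------
# fitting


def test_mle_matches_grid_search_oracle():
    """Half-normal MLE on three distances vs 0.01-m grid over sigma."""
    x = np.array([50.0, 100.0, 150.0])
    w = 500.0
    fit = det.fit_detection(x, "half_normal", w)
    sigmas = np.arange(10.0, 1000.0, 0.01)
    mu = sigmas * np.sqrt(np.pi / 2) * special.erf(w / (sigmas * np.sqrt(2)))
    ll = -np.sum(x**2)[None] / (2 * sigmas**2) - len(x) * np.log(mu)
    sigma_grid = sigmas[np.argmax(ll)]
    assert np.exp(fit.beta[0]) == pytest.approx(sigma_grid, abs=0.1)


def test_half_normal_parameter_recovery():
    x = simulate_distances(2000, "half_normal", 150.0, 500.0, seed=7)
    fit = det.fit_detection(x, "half_normal", 500.0)
    assert np.exp(fit.beta[0]) == pytest.approx(150.0, rel=0.05)
    assert np.all((fit.p_i > 0) & (fit.p_i <= 1))
    assert 0 < fit.p_bar <= 1
    assert fit.cv_det >= 0


def test_aic_prefers_true_key():
    """On half-normal truth, AIC favours half-normal over hazard rate in a
    majority of replicates."""
    wins = 0
    n_rep = 20
    for s in range(n_rep):
        x = simulate_distances(300, "half_normal", 150.0, 500.0, seed=100 + s)
        hn = det.fit_detection(x, "half_normal", 500.0)
        hr = det.fit_detection(x, "hazard_rate", 500.0)
        wins += hn.aic < hr.aic
    assert wins > n_rep / 2


def test_loglik_scale_invariance():
    """Rescaling distances and w by c shifts loglik by -n log c, so AIC
    differences between keys are unit-invariant."""
    x = simulate_distances(300, "hazard_rate", 200.0, 500.0, b=2.5, seed=3)
    c = 0.001  # metres -> kilometres
    fits = {}
    for key in det.KEYS:
        f1 = det.fit_detection(x, key, 500.0)
        f2 = det.fit_detection(x * c, key, 500.0 * c)
        assert f2.loglik == pytest.approx(f1.loglik - len(x) * np.log(c), abs=1e-3)
        fits[key] = (f1, f2)
    d1 = fits["half_normal"][0].aic - fits["hazard_rate"][0].aic
    d2 = fits["half_normal"][1].aic - fits["hazard_rate"][1].aic
    assert d1 == pytest.approx(d2, abs=1e-2)


def test_covariate_effect_recovery():
    """Sea-state effect on the detection scale is recovered in sign and
    rough magnitude."""
    rng = np.random.default_rng(5)
    sea = rng.integers(0, 5, 1500)
    sigma = 250.0 * np.exp(-0.15 * sea)
    xs = np.concatenate(
        [simulate_distances(1, "half_normal", s, 500.0, seed=i) for i, s in enumerate(sigma)]
    )
    Z = np.column_stack([np.ones(len(sea)), sea])
    fit = det.fit_detection(xs, "half_normal", 500.0, Z, ["(intercept)", "sea_state"])
    assert np.exp(fit.beta[0]) == pytest.approx(250.0, rel=0.10)
    assert fit.beta[1] == pytest.approx(-0.15, abs=0.05)


def test_fit_rejects_out_of_range_distances():
    with pytest.raises(ValueError):
        det.fit_detection(np.array([10.0, 600.0, 20.0, 30.0]), "half_normal", 500.0)


def test_hazard_shape_boundary_warns():
    # distances that look uniform push the hazard shape to its floor
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 500.0, 80)
    with pytest.warns(UserWarning, match="lower bound|information"):
        det.fit_detection(x, "hazard_rate", 500.0)


# ---------------------------------------------------------------------------
# average detection probability


def test_average_p_equals_common_p_without_covariates():
    x = simulate_distances(400, "half_normal", 180.0, 500.0, seed=11)
    fit = det.fit_detection(x, "half_normal", 500.0)
    # intercept-only: every p_i identical, so the HT average equals it
    assert np.ptp(fit.p_i) < 1e-12
    p_bar, cv = det.average_p(fit)
    assert p_bar == pytest.approx(fit.p_i[0], rel=1e-9)
    assert cv > 0


def test_cv_zero_when_vcov_zero():
    x = simulate_distances(200, "half_normal", 180.0, 500.0, seed=12)
    fit = det.fit_detection(x, "half_normal", 500.0)
    fit.vcov = np.zeros_like(fit.vcov)
    grad_var = fit.vcov.sum()
    assert grad_var == 0.0  # delta method then gives exactly zero variance


def test_delta_cv_agrees_with_transect_bootstrap():
    x = simulate_distances(500, "half_normal", 180.0, 500.0, seed=13)
    fit = det.fit_detection(x, "half_normal", 500.0)
    tids = np.repeat(np.arange(25), 20)  # 25 pseudo-transects
    cv_boot = det.bootstrap_cv(fit, tids, n_boot=300, seed=1)
    assert fit.cv_det == pytest.approx(cv_boot, rel=0.20)


# ---------------------------------------------------------------------------
# goodness of fit


def test_cvm_statistic_formula():
    assert det.cvm_statistic(np.array([0.5])) == pytest.approx(1.0 / 12.0)


def test_ks_statistic_direct_sup():
    assert det.ks_statistic(np.array([0.25, 0.5, 0.75])) == pytest.approx(0.25)


def test_gof_on_well_specified_fit():
    x = simulate_distances(400, "hazard_rate", 200.0, 500.0, b=2.5, seed=21)
    fit = det.fit_detection(x, "hazard_rate", 500.0)
    g = fit.gof
    assert set(g) == {"ks_stat", "ks_p", "cvm_stat", "cvm_p"}
    assert g["ks_p"] > 0.01 and g["cvm_p"] > 0.01  # true model should fit
    assert 0 <= g["ks_stat"] <= 1


def test_gof_requires_two_observations():
    x = simulate_distances(5, "half_normal", 200.0, 500.0, seed=2)
    fit = det.fit_detection(x, "half_normal", 500.0)
    fit.n = 1
    with pytest.raises(ValueError):
        det.gof(fit)


# ---------------------------------------------------------------------------
# model selection


def _stub_fit(aic, n_params, w=500.0, n=100):
    f = det.DetectionFit(
        key="half_normal", beta=np.array([5.0]), b=None, w=w,
        covariate_names=["(intercept)"], vcov=np.eye(1), loglik=0.0, aic=aic,
        n=n, p_i=np.full(n, 0.5), sigma_i=np.full(n, 150.0), p_bar=0.5,
        cv_det=0.1, distances=np.zeros(n), Z=np.ones((n, 1)), n_params=n_params,
    )
    return f


def test_select_best_penalizes_parameters_on_ties():
    # equal loglik, k = 2 vs 3 -> AIC = -2ll + 2k favours k = 2
    f2 = _stub_fit(aic=104.0, n_params=2)
    f3 = _stub_fit(aic=106.0, n_params=3)
    assert det.select_best([f3, f2]) is f2
    # exact AIC tie -> fewer parameters wins
    g3 = _stub_fit(aic=104.0, n_params=3)
    assert det.select_best([g3, f2]) is f2


def test_select_best_single_candidate_and_guards():
    f = _stub_fit(100.0, 1)
    assert det.select_best([f]) is f
    with pytest.raises(ValueError):
        det.select_best([])
    with pytest.raises(ValueError):
        det.select_best([f, _stub_fit(90.0, 1, w=400.0)])


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_simulated_distances_within_strip(seed):
    x = simulate_distances(50, "hazard_rate", 200.0, 500.0, b=2.5, seed=seed)
    assert np.all((x >= 0) & (x <= 500.0))
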