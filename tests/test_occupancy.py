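import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import occuscale as oc
from occuscale.occupancy import (
    DetectionHistory, FitResult, ModelSpec, build_detection_matrix, fit_occupancy,
    negloglik, predict_psi, simulate_from_fit, wald_inference,
)
from conftest import make_station_table


def hist_of(matrix):
    m = np.asarray(matrix, dtype=float)
    return DetectionHistory([f"s{i}" for i in range(m.shape[0])], m)


def brute_negloglik(params, hist, X_psi, X_p):
    """z-enumeration oracle: marginalise the latent state site by site."""
    psi = expit(X_psi @ params[:X_psi.shape[1]])
    p = expit(X_p @ params[X_psi.shape[1]:])
    total = 0.0
    for i in range(hist.n_sites):
        L = 0.0
        for z in (0, 1):
            term = psi[i] if z else 1 - psi[i]
            for k in range(hist.n_occasions):
                y = hist.matrix[i, k]
                if np.isnan(y):
                    continue
                pik = p[i] * z
                term *= pik if y == 1 else (1 - pik)
            L += term
        total += np.log(L)
    return -total


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_negloglik_hand_cases():
    # one site, history [0,0], psi = p = 0.5: L = 0.5*0.25 + 0.5 = 0.625
    h = hist_of([[0, 0]])
    X1 = np.ones((1, 1))
    nll = negloglik(np.array([0.0, 0.0]), h, X1, X1)
    assert nll == pytest.approx(-np.log(0.625), abs=1e-12)
    # one site, history [1], psi = 0.5, p = 1: detection forces z = 1, L = 0.5
    h = hist_of([[1]])
    nll = negloglik(np.array([0.0, 50.0]), h, X1, X1)
    assert nll == pytest.approx(-np.log(0.5), abs=1e-9)


def test_negloglik_matches_enumeration_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        n = int(rng.integers(1, 13))
        K = int(rng.integers(1, 6))
        m = rng.choice([0.0, 1.0, np.nan], size=(n, K), p=[0.5, 0.3, 0.2])
        m[np.all(np.isnan(m), axis=1), 0] = 0.0  # keep every site usable
        h = hist_of(m)
        kb = int(rng.integers(1, 3))
        X_psi = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(kb - 1)])
        X_p = np.ones((n, 1))
        th = rng.normal(scale=1.2, size=kb + 1)
        assert negloglik(th, h, X_psi, X_p) == pytest.approx(
            brute_negloglik(th, h, X_psi, X_p), abs=1e-10)


def test_negloglik_rejects_nonfinite_params():
    h = hist_of([[0, 1]])
    with pytest.raises(ValueError):
        negloglik(np.array([np.inf, 0.0]), h, np.ones((1, 1)), np.ones((1, 1)))


# ---------------------------------------------------------------------------
# detection matrix construction
# ---------------------------------------------------------------------------

def _one_station(days, reserve="A"):
    return oc.StationSet(pd.DataFrame({
        "id": ["s1"], "x": [0.0], "y": [0.0], "reserve": [reserve], "on_road": [False],
        "deploy_start": [pd.Timestamp("2024-01-01")],
        "deploy_end": [pd.Timestamp("2024-01-01") + pd.Timedelta(days=days - 1)],
    }))


def test_bin_arithmetic_single_record():
    st = _one_station(12)
    rec = pd.DataFrame({"station": ["s1"], "species": ["civet"],
                        "date": [pd.Timestamp("2024-01-04")]})  # day 3 of days 0-11
    h = build_detection_matrix(rec, st, ["civet"], occasion_length=6)
    assert h.matrix.tolist() == [[1.0, 0.0]]


def test_42_day_deployment_gives_7_occasions():
    st = _one_station(42)
    rec = pd.DataFrame({"station": [], "species": [], "date": []})
    h = build_detection_matrix(rec, st, ["civet"], occasion_length=6)
    assert h.n_occasions == 7
    assert (h.matrix == 0.0).all()


def test_short_deployment_pads_missing_for_later_occasions():
    df = pd.concat([_one_station(6).df, _one_station(18).df]).reset_index(drop=True)
    df.loc[1, "id"] = "s2"
    st = oc.StationSet(df)
    rec = pd.DataFrame({"station": [], "species": [], "date": []})
    h = build_detection_matrix(rec, st, ["civet"], occasion_length=6)
    assert h.n_occasions == 3
    row = h.matrix[h.sites.index("s1")]
    assert row[0] == 0.0 and np.isnan(row[1]) and np.isnan(row[2])


def test_species_pooling_and_window_filtering():
    st = _one_station(12)
    rec = pd.DataFrame({
        "station": ["s1", "s1", "s1"],
        "species": ["greater_chevrotain", "lesser_chevrotain", "macaque"],
        "date": pd.to_datetime(["2024-01-02", "2024-01-09", "2024-01-03"]),
    })
    h = build_detection_matrix(rec, st, ["greater_chevrotain", "lesser_chevrotain"], 6)
    assert h.matrix.tolist() == [[1.0, 1.0]]
    # record outside the deployment window is dropped with a warning
    late = pd.DataFrame({"station": ["s1"], "species": ["civet"],
                         "date": [pd.Timestamp("2024-03-01")]})
    with pytest.warns(UserWarning, match="outside deployment"):
        h2 = build_detection_matrix(late, st, ["civet"], 6)
    assert (h2.matrix == 0.0).all()


def test_unknown_station_errors():
    st = _one_station(12)
    rec = pd.DataFrame({"station": ["ghost"], "species": ["civet"],
                        "date": [pd.Timestamp("2024-01-02")]})
    with pytest.raises(KeyError, match="ghost"):
        build_detection_matrix(rec, st, ["civet"], 6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _grid_search_constant(hist, grid_n=200):
    """2-D likelihood grid oracle for the constant-constant model."""
    best = (np.inf, None, None)
    X1 = np.ones((hist.n_sites, 1))
    for psi in np.linspace(0.02, 0.98, grid_n):
        for p in np.linspace(0.02, 0.98, grid_n):
            nll = negloglik(np.array([logit(psi), logit(p)]), hist, X1, X1)
            if nll < best[0]:
                best = (nll, psi, p)
    return best


def test_constant_model_recovery_against_grid_oracle():
    rng = np.random.default_rng(31)
    n, K = 5000, 7
    z = rng.random(n) < 0.6
    y = (rng.random((n, K)) < 0.4 * z[:, None]).astype(float)
    hist = hist_of(y)
    fit = fit_occupancy(hist, ModelSpec())
    psi_hat = float(expit(fit.beta[0]))
    p_hat = float(expit(fit.gamma[0]))
    assert abs(psi_hat - 0.6) < 0.03 and abs(p_hat - 0.4) < 0.03
    nll_grid, psi_g, p_g = _grid_search_constant(hist, grid_n=120)
    assert abs(psi_hat - psi_g) < 0.01 and abs(p_hat - p_g) < 0.01
    assert -fit.loglik <= nll_grid + 1e-6


def test_aic_identity_and_multistart_stability():
    rng = np.random.default_rng(5)
    y = (rng.random((80, 5)) < 0.3).astype(float)
    hist = hist_of(y)
    fits = [fit_occupancy(hist, ModelSpec(), seed=s) for s in range(5)]
    logliks = [f.loglik for f in fits]
    assert max(logliks) - min(logliks) < 1e-6
    for f in fits:
        assert f.AIC == pytest.approx(-2 * f.loglik + 2 * f.K, abs=1e-12)
        assert f.K == len(f.beta) + len(f.gamma)


def test_site_order_invariance_constant_model():
    rng = np.random.default_rng(6)
    z = rng.random(60) < 0.6
    y = (rng.random((60, 6)) < 0.4 * z[:, None]).astype(float)
    hist = hist_of(y)
    perm = rng.permutation(60)
    hist_perm = DetectionHistory([hist.sites[i] for i in perm], hist.matrix[perm])
    f1 = fit_occupancy(hist, ModelSpec())
    f2 = fit_occupancy(hist_perm, ModelSpec())
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


def test_standardization_invariance():
    """Fitted log-likelihood is unchanged by covariate standardization and
    the slope rescales by the covariate SD."""
    rng = np.random.default_rng(7)
    st = make_station_table(200, rng)
    x = rng.normal(10.0, 4.0, 200)
    cov = oc.CovariateTable(pd.DataFrame({"x": x}, index=pd.Index(st.df["id"], name="station")))
    truth = oc.TrueModel(0.2, 0.9, "x", -0.3, seed=3)
    hist = oc.simulate_detection_history(st, cov, truth, n_occasions=7, missing_rate=0.05)
    spec = ModelSpec(("x",))
    f_std = fit_occupancy(hist, spec, covariates=cov, standardize=True)
    f_raw = fit_occupancy(hist, spec, covariates=cov, standardize=False)
    assert f_std.loglik == pytest.approx(f_raw.loglik, abs=1e-6)
    sd = x.std(ddof=1)
    assert f_std.beta[1] == pytest.approx(f_raw.beta[1] * sd, rel=1e-3)


def test_all_missing_site_dropped_with_warning():
    m = np.array([[0.0, 1.0], [np.nan, np.nan]])
    hist = DetectionHistory(["a", "b"], m)
    with pytest.warns(UserWarning, match="dropping"):
        fit = fit_occupancy(hist, ModelSpec())
    assert fit.n_sites == 1


# ---------------------------------------------------------------------------
# Wald inference, prediction, simulation
# ---------------------------------------------------------------------------

def _manual_fit(beta, gamma, vcov, psi_names, p_names, n=4):
    return FitResult(
        spec=ModelSpec(), beta=np.asarray(beta, float), gamma=np.asarray(gamma, float),
        vcov=vcov, loglik=-10.0, K=len(beta) + len(gamma),
        AIC=20.0 + 2 * (len(beta) + len(gamma)), converged=True, n_sites=n, n_obs=n,
        psi_names=psi_names, p_names=p_names,
        X_psi=np.ones((n, len(beta))), X_p=np.ones((n, len(gamma))),
    )


def test_wald_cv_matches_reported_convention():
    """CV = SE/|estimate|: a slope of -3.59 with SE 0.92 gives CV 0.26."""
    fit = _manual_fit([-1.0, -3.59], [0.5], np.diag([0.1 ** 2, 0.92 ** 2, 0.2 ** 2]),
                      ["psi_(Intercept)", "psi_x"], ["p_(Intercept)"])
    tab = wald_inference(fit)
    assert round(float(tab.loc["psi_x", "CV"]), 2) == 0.26
    # z = 1.96 -> p ~ 0.05
    fit2 = _manual_fit([1.96], [0.0], np.diag([1.0, 1.0]), ["psi_(Intercept)"], ["p_(Intercept)"])
    tab2 = wald_inference(fit2)
    assert float(tab2.loc["psi_(Intercept)", "p_value"]) == pytest.approx(0.05, abs=0.001)
    # zero estimate -> CV undefined
    assert np.isnan(tab2.loc["p_(Intercept)", "CV"])


def test_predict_psi_inverse_logit():
    df = pd.DataFrame({"x": [-1.0, 0.0, 2.0]}, index=["a", "b", "c"])
    fit = _manual_fit([0.0], [0.0], None, ["psi_(Intercept)"], ["p_(Intercept)"], n=3)
    assert np.allclose(predict_psi(fit, df), 0.5)
    fit2 = FitResult(
        spec=ModelSpec(("x",)), beta=np.array([0.0, 1.0]), gamma=np.array([0.0]),
        vcov=None, loglik=-1.0, K=3, AIC=8.0, converged=True, n_sites=3, n_obs=3,
        psi_names=["psi_(Intercept)", "psi_x"], p_names=["p_(Intercept)"],
        X_psi=np.ones((3, 2)), X_p=np.ones((3, 1)),
    )
    got = predict_psi(fit2, df)
    assert np.allclose(got, expit(np.array([-1.0, 0.0, 2.0])))
    with pytest.raises(KeyError):
        predict_psi(fit2, pd.DataFrame({"other": [1.0]}))


def test_simulate_from_fit_preserves_missingness_and_seed():
    rng = np.random.default_rng(9)
    m = rng.choice([0.0, 1.0, np.nan], size=(40, 6), p=[0.5, 0.3, 0.2])
    m[np.all(np.isnan(m), axis=1), 0] = 0.0
    hist = hist_of(m)
    fit = fit_occupancy(hist, ModelSpec())
    a = simulate_from_fit(fit, hist, seed=4)
    b = simulate_from_fit(fit, hist, seed=4)
    assert np.array_equal(a.matrix, b.matrix, equal_nan=True)
    assert np.array_equal(np.isnan(a.matrix), np.isnan(hist.matrix))


def test_simulated_naive_occupancy_matches_closed_form():
    """Mean naive occupancy over many draws equals
    mean_i psi_i (1 - prod_k (1 - p_ik)) over observed occasions."""
    rng = np.random.default_rng(10)
    z = rng.random(60) < 0.7
    y = (rng.random((60, 5)) < 0.35 * z[:, None]).astype(float)
    hist = hist_of(y)
    fit = fit_occupancy(hist, ModelSpec())
    psi, p = fit.psi_hat, fit.p_hat
    k_obs = hist.observed.sum(axis=1)
    expect = float((psi * (1 - (1 - p) ** k_obs)).mean())
    draws = [simulate_from_fit(fit, hist, seed=s).naive_occupancy() for s in range(1000)]
    mc = float(np.mean(draws))
    site_var = (psi * (1 - (1 - p) ** k_obs) * (1 - psi * (1 - (1 - p) ** k_obs))).sum() / 60 ** 2
    sd = np.sqrt(site_var / 1000)
    assert abs(mc - expect) < 3 * sd
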