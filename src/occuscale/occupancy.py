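"""Single-season site-occupancy model with imperfect detection.

The model has two Bernoulli stages: the latent occupancy state of site *i*
is z_i ~ Bernoulli(psi_i), and the detection y_ik on occasion *k* is
y_ik | z_i ~ Bernoulli(p_ik * z_i).  Both psi and p are logit-linear in
covariates: logit(psi_i) = beta0 + beta1 x_i, logit(p_ik) = gamma'w_ik.
Marginalising z gives the site likelihood

    L_i = psi_i * prod_{k in obs(i)} p_ik^y_ik (1 - p_ik)^(1 - y_ik)
          + (1 - psi_i) * I(all observed y_ik = 0),

with missing occasions dropped from the product.  Fitting is by numerical
maximum likelihood from multiple dispersed starts; standard errors come
from the inverse of the numerically differentiated Hessian (Wald).

Detection covariates are the station-level design used in camera-trap
studies: camera position on/off road, and forest reserve as a factor.
Occupancy covariates come from a :class:`~occuscale.covariates.CovariateTable`
and are z-score standardized by default before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "DetectionHistory",
    "ModelSpec",
    "FitResult",
    "build_detection_matrix",
    "negloglik",
    "fit_occupancy",
    "wald_inference",
    "predict_psi",
    "simulate_from_fit",
]

BOUNDARY = 10.0  # |coef| beyond this on the logit scale flags separation


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Sites x occasions detection/non-detection matrix over {0, 1, missing}.

    ``matrix`` is float with ``nan`` marking occasions on which the cameras
    were not operational.  ``occasion_dates`` optionally carries the
    (start, end) date of each occasion column per study area.
    """

    sites: list[str]
    matrix: np.ndarray
    occasion_length: int = 6
    occasion_dates: dict | None = None
    true_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.sites):
            raise ValueError("matrix must be n_sites x n_occasions")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("matrix values must be 0, 1 or missing")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.matrix)

    def naive_occupancy(self) -> float:
        """Fraction of sites with >= 1 detection (no detection correction)."""
        det = np.nansum(self.matrix, axis=1) > 0
        return float(det.mean())

    def drop_all_missing_sites(self) -> "DetectionHistory":
        keep = self.observed.any(axis=1)
        if keep.all():
            return self
        warnings.warn(f"dropping {int((~keep).sum())} site(s) with no operational occasion", stacklevel=2)
        return DetectionHistory(
            [s for s, k in zip(self.sites, keep) if k],
            self.matrix[keep],
            self.occasion_length,
            self.occasion_dates,
            self.true_z[keep] if self.true_z is not None else None,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.matrix, index=pd.Index(self.sites, name="site"),
            columns=[f"o{k + 1}" for k in range(self.n_occasions)],
        ).astype("Int64")  # 0/1/NA, not floats
        df.to_csv(path, na_rep="NA")


@dataclass(frozen=True)
class ModelSpec:
    """Occupancy/detection model formula.

    ``psi_terms``: names of occupancy covariates (intercept implicit; the
    study design uses at most one).  ``p_terms``: subset of
    {"road", "reserve"} (intercept implicit).
    """

    psi_terms: tuple[str, ...] = ()
    p_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.p_terms) - {"road", "reserve"}
        if bad:
            raise ValueError(f"unknown detection terms: {sorted(bad)}")

    def label(self) -> str:
        psi = "+".join(self.psi_terms) if self.psi_terms else "1"
        p = "+".join(self.p_terms) if self.p_terms else "1"
        return f"psi({psi}) p({p})"


@dataclass(eq=False)
class FitResult:
    """Maximum-likelihood fit of a single-season occupancy model."""

    spec: ModelSpec
    beta: np.ndarray
    gamma: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    K: int
    AIC: float
    converged: bool
    n_sites: int
    n_obs: int
    psi_names: list[str] = field(default_factory=list)
    p_names: list[str] = field(default_factory=list)
    standardization: dict = field(default_factory=dict)
    boundary: bool = False
    message: str = ""
    # design matrices retained so the fit can be re-simulated and re-fit
    # (parametric bootstrap) without re-deriving covariates
    X_psi: np.ndarray | None = None
    X_p: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma])

    @property
    def psi_hat(self) -> np.ndarray:
        return expit(self.X_psi @ self.beta)

    @property
    def p_hat(self) -> np.ndarray:
        """Per-site detection probability (constant across occasions for
        station-level detection covariates)."""
        return expit(self.X_p @ self.gamma)


# ---------------------------------------------------------------------------
# Detection-matrix construction from camera-trap records
# ---------------------------------------------------------------------------

def build_detection_matrix(
    records: pd.DataFrame,
    stations,
    species: list[str],
    occasion_length: int = 6,
) -> DetectionHistory:
    """Bin dated camera-trap records into a site-by-occasion 0/1/NA matrix.

    Occasions partition [earliest deployment start, latest deployment end]
    of each study area (reserve) into consecutive ``occasion_length``-day
    bins (the final bin may be short).  A cell is 1 if any record of a
    listed species (multiple names pool, e.g. both chevrotain species) falls
    at that station in that bin, 0 if the station was operational at least
    one day of the bin, and missing otherwise.
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1")
    sdf = stations.df if hasattr(stations, "df") else stations
    sdf = sdf.copy()
    sdf["deploy_start"] = pd.to_datetime(sdf["deploy_start"])
    sdf["deploy_end"] = pd.to_datetime(sdf["deploy_end"])
    known = set(sdf["id"])
    unknown = set(records["station"]) - known
    if unknown:
        raise KeyError(f"records reference unknown station id(s): {sorted(unknown)}")

    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec = rec[rec["species"].isin(species)]
    # drop records outside their station's deployment window
    win = sdf.set_index("id")[["deploy_start", "deploy_end"]]
    starts = win.loc[rec["station"], "deploy_start"].to_numpy()
    ends = win.loc[rec["station"], "deploy_end"].to_numpy()
    ok = (rec["date"].to_numpy() >= starts) & (rec["date"].to_numpy() <= ends)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} record(s) outside deployment windows", stacklevel=2)
        rec = rec[ok]

    # per-area occasion calendars anchored at the area's earliest deployment
    calendars: dict = {}
    for area, grp in sdf.groupby("reserve"):
        t0 = grp["deploy_start"].min()
        t1 = grp["deploy_end"].max()
        n_occ = int(np.ceil(((t1 - t0).days + 1) / occasion_length))
        calendars[area] = (t0, n_occ)
    max_occ = max(n for _, n in calendars.values())

    mat = np.full((len(sdf), max_occ), np.nan)
    site_ids = sdf["id"].tolist()
    rec_by_station = dict(tuple(rec.groupby("station")))
    for i, row in enumerate(sdf.itertuples()):
        t0, n_occ = calendars[row.reserve]
        for k in range(n_occ):
            bin_start = t0 + pd.Timedelta(days=k * occasion_length)
            bin_end = bin_start + pd.Timedelta(days=occasion_length - 1)
            # operational >= 1 day of the bin
            if row.deploy_start <= bin_end and row.deploy_end >= bin_start:
                mat[i, k] = 0.0
        r = rec_by_station.get(row.id)
        if r is not None:
            occ = ((r["date"] - t0).dt.days // occasion_length).to_numpy()
            for k in occ:
                if 0 <= k < max_occ and not np.isnan(mat[i, k]):
                    mat[i, k] = 1.0
    return DetectionHistory(site_ids, mat, occasion_length).drop_all_missing_sites()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _site_loglik(psi, p, y, obs):
    """Vector of per-site log marginal likelihoods.

    ``p`` may be (n,) site-level or (n, K) site-by-occasion.
    """
    y0 = np.where(obs, y, 0.0)
    if p.ndim == 1:
        p2 = np.broadcast_to(p[:, None], y.shape)
    else:
        p2 = p
    with np.errstate(divide="ignore"):
        logp = np.where(obs & (y0 == 1.0), np.log(p2), 0.0)
        log1p = np.where(obs & (y0 == 0.0), np.log1p(-p2), 0.0)
    det_ll = (logp + log1p).sum(axis=1)
    never = (y0 * obs).sum(axis=1) == 0
    # L = psi*exp(det_ll) + (1-psi)*never  (guard exp underflow via logaddexp)
    with np.errstate(divide="ignore"):
        a = np.log(psi) + det_ll
        b = np.where(never, np.log1p(-psi), -np.inf)
    return np.logaddexp(a, b)


def negloglik(params: np.ndarray, history: DetectionHistory, X_psi: np.ndarray, X_p: np.ndarray) -> float:
    """Negative log-likelihood of the single-season occupancy model.

    ``params`` concatenates beta (len = X_psi columns) and gamma (len = X_p
    columns); missing occasions are excluded from the detection product.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    kb = X_psi.shape[1]
    if params.size != kb + X_p.shape[1]:
        raise ValueError(f"expected {kb + X_p.shape[1]} parameters, got {params.size}")
    psi = expit(X_psi @ params[:kb])
    p = expit(X_p @ params[kb:])
    ll = _site_loglik(psi, p, np.nan_to_num(history.matrix), history.observed)
    return float(-ll.sum())


def _design_matrices(history, spec, covariates, stations):
    """Build (X_psi, X_p, names, standardization record) for a model spec."""
    n = history.n_sites
    X_psi = [np.ones(n)]
    psi_names = ["psi_(Intercept)"]
    standardization = {}
    for term in spec.psi_terms:
        if covariates is None:
            raise KeyError(f"occupancy covariate {term!r} requires a covariate table")
        col = _resolve_series(covariates, term, history.sites)
        if col.isna().any():
            bad = [s for s, v in zip(history.sites, col) if pd.isna(v)]
            raise ValueError(f"missing value for covariate {term!r} at station(s) {bad[:5]}")
        x = col.to_numpy(float)
        rec = {"mean": float(x.mean()), "sd": float(x.std(ddof=1))}
        standardization[term] = rec
        X_psi.append(x)
        psi_names.append(f"psi_{term}")
    X_p = [np.ones(n)]
    p_names = ["p_(Intercept)"]
    if spec.p_terms:
        sdf = (stations.df if hasattr(stations, "df") else stations).set_index("id").loc[history.sites]
        if "road" in spec.p_terms:
            X_p.append(sdf["on_road"].to_numpy(float))
            p_names.append("p_road")
        if "reserve" in spec.p_terms:
            levels = sorted(sdf["reserve"].unique())
            for lev in levels[1:]:  # treatment coding, first level reference
                X_p.append((sdf["reserve"] == lev).to_numpy(float))
                p_names.append(f"p_reserve[{lev}]")
    return np.column_stack(X_psi), np.column_stack(X_p), psi_names, p_names, standardization


def _resolve_series(covariates, term, sites) -> pd.Series:
    df = covariates.data if hasattr(covariates, "data") else covariates
    if term not in df.columns:
        raise KeyError(f"unknown covariate {term!r}")
    return df[term].reindex(sites)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_occupancy(
    history: DetectionHistory,
    spec: ModelSpec,
    covariates=None,
    stations=None,
    standardize: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit from multiple dispersed random starts.

    Continuous occupancy covariates are z-score standardized before fitting
    when ``standardize`` is on (the default); the per-covariate mean/SD is
    recorded in the result so predictions apply the identical transform.
    The variance-covariance matrix is the inverse of a central-difference
    Hessian at the optimum; a non-positive-definite Hessian or optimizer
    failure yields ``converged=False`` rather than an exception, and
    estimates beyond |coef| > 10 on the logit scale are flagged as boundary
    (complete-separation) estimates.
    """
    history = history.drop_all_missing_sites()
    if history.n_sites < 1:
        raise ValueError("no usable sites")
    X_psi, X_p, psi_names, p_names, stdrec = _design_matrices(history, spec, covariates, stations)
    if standardize:
        for j, term in enumerate(spec.psi_terms, start=1):
            rec = stdrec[term]
            if rec["sd"] == 0:
                raise ValueError(f"covariate {term!r} is constant; cannot standardize")
            X_psi[:, j] = (X_psi[:, j] - rec["mean"]) / rec["sd"]
            rec["applied"] = True
    K = X_psi.shape[1] + X_p.shape[1]

    rng = np.random.default_rng(seed)
    y = np.nan_to_num(history.matrix)
    obs = history.observed
    # moment-based warm start: naive occupancy and raw detection frequency
    naive = min(max(history.naive_occupancy(), 0.05), 0.95)
    praw = min(max(float(y[obs].mean()), 0.02), 0.98)
    warm = np.zeros(K)
    warm[0] = np.log(naive / (1 - naive))
    warm[X_psi.shape[1]] = np.log(praw / (1 - praw))

    starts = [warm] if start is None else [np.asarray(start, float), warm]
    while len(starts) < max(n_starts, 1):
        starts.append(warm + rng.normal(0.0, 1.5, size=K))

    obj = lambda th: negloglik(th, history, X_psi, X_p)
    best = _optimize(obj, starts)
    theta = best.x
    loglik = -float(best.fun)

    vcov, pd_ok = _hessian_vcov(obj, theta)
    converged = bool(best.success) and pd_ok
    boundary = bool(np.any(np.abs(theta) > BOUNDARY))
    kb = X_psi.shape[1]
    return FitResult(
        spec=spec,
        beta=theta[:kb].copy(),
        gamma=theta[kb:].copy(),
        vcov=vcov,
        loglik=loglik,
        K=K,
        AIC=-2.0 * loglik + 2.0 * K,
        converged=converged,
        n_sites=history.n_sites,
        n_obs=int(obs.sum()),
        psi_names=psi_names,
        p_names=p_names,
        standardization=stdrec,
        boundary=boundary,
        message=str(best.message),
        X_psi=X_psi,
        X_p=X_p,
    )


def _optimize(obj, starts):
    """Quasi-Newton minimisation over multiple starts; the best optimum is
    re-polished once if its run terminated abnormally (line-search noise at
    an already-converged point should not flag non-convergence)."""
    opts = {"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500}
    best = None
    for s in starts:
        res = optimize.minimize(obj, s, method="L-BFGS-B", options=opts)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if not best.success:
        res = optimize.minimize(obj, best.x, method="L-BFGS-B", options=opts)
        if res.fun <= best.fun + 1e-9:
            best = res
    return best


def refit_with_designs(
    fit: FitResult,
    history: DetectionHistory,
    n_starts: int = 2,
    seed: int = 0,
    start: np.ndarray | None = None,
    compute_vcov: bool = False,
) -> FitResult:
    """Refit the same model on a new history using the design matrices
    stored in ``fit`` (the parametric-bootstrap refit path: covariates and
    their standardization are frozen, only the detection data change)."""
    if fit.X_psi is None or fit.X_p is None:
        raise ValueError("fit does not carry design matrices")
    X_psi, X_p = fit.X_psi, fit.X_p
    K = X_psi.shape[1] + X_p.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.asarray(start, float) if start is not None else fit.params, np.zeros(K)]
    while len(starts) < max(n_starts, 1):
        starts.append(fit.params + rng.normal(0.0, 1.0, size=K))
    obj = lambda th: negloglik(th, history, X_psi, X_p)
    best = _optimize(obj, starts[:max(n_starts, 1)])
    theta = best.x
    loglik = -float(best.fun)
    if compute_vcov:
        vcov, pd_ok = _hessian_vcov(obj, theta)
    else:
        vcov, pd_ok = None, True
    kb = X_psi.shape[1]
    return FitResult(
        spec=fit.spec, beta=theta[:kb].copy(), gamma=theta[kb:].copy(), vcov=vcov,
        loglik=loglik, K=K, AIC=-2.0 * loglik + 2.0 * K,
        converged=bool(best.success) and pd_ok,
        n_sites=history.n_sites, n_obs=int(history.observed.sum()),
        psi_names=list(fit.psi_names), p_names=list(fit.p_names),
        standardization=dict(fit.standardization),
        boundary=bool(np.any(np.abs(theta) > BOUNDARY)),
        message=str(best.message), X_psi=X_psi, X_p=X_p,
    )


def _hessian_vcov(obj, theta, eps: float = 1e-5):
    """Central-difference Hessian of the negative log-likelihood; returns
    (vcov, positive_definite_flag)."""
    k = theta.size
    h = np.empty((k, k))
    steps = eps * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = obj(theta + ei + ej)
            fpm = obj(theta + ei - ej)
            fmp = obj(theta - ei + ej)
            fmm = obj(theta - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        eigvals = np.linalg.eigvalsh(h)
        if eigvals.min() <= 0:
            return None, False
        return np.linalg.inv(h), True
    except np.linalg.LinAlgError:
        return None, False


# ---------------------------------------------------------------------------
# Inference, prediction, simulation
# ---------------------------------------------------------------------------

def wald_inference(fit: FitResult) -> pd.DataFrame:
    """Per-coefficient Wald table: estimate, SE, z, two-sided p, and CV.

    CV (coefficient of variation) = SE / |estimate|, the precision measure
    reported alongside occupancy-covariate slopes; undefined (missing) for a
    zero estimate.  With an invalid covariance matrix the SEs are missing.
    """
    names = fit.psi_names + fit.p_names
    est = fit.params
    if fit.vcov is not None:
        se = np.sqrt(np.diag(fit.vcov))
    else:
        se = np.full(est.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        cv = np.where(est != 0, se / np.abs(est), np.nan)
    return pd.DataFrame(
        {"estimate": est, "SE": se, "z": z, "p_value": p, "CV": cv},
        index=pd.Index(names, name="coefficient"),
    )


def predict_psi(fit: FitResult, covariates) -> pd.Series:
    """Occupancy probability per station from a fitted model, applying the
    training standardization to the supplied covariate values."""
    df = covariates.data if hasattr(covariates, "data") else covariates
    X = [np.ones(len(df))]
    for term in fit.spec.psi_terms:
        if term not in df.columns:
            raise KeyError(f"unknown covariate {term!r}")
        x = df[term].to_numpy(float)
        rec = fit.standardization.get(term, {})
        if rec.get("applied"):
            x = (x - rec["mean"]) / rec["sd"]
        X.append(x)
    return pd.Series(expit(np.column_stack(X) @ fit.beta), index=df.index, name="psi_hat")


def simulate_from_fit(fit: FitResult, template: DetectionHistory, seed: int) -> DetectionHistory:
    """Parametric draw of a detection history from the fitted (psi_hat,
    p_hat), preserving the template's missingness pattern exactly."""
    if not fit.converged:
        warnings.warn("simulating from a non-converged fit", stacklevel=2)
    rng = np.random.default_rng(seed)
    n, K = template.matrix.shape
    z = rng.random(n) < fit.psi_hat
    p = fit.p_hat
    y = (rng.random((n, K)) < (p[:, None] * z[:, None])).astype(float)
    y[~template.observed] = np.nan
    return DetectionHistory(template.sites, y, template.occasion_length, template.occasion_dates,
                            true_z=z.astype(float))
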