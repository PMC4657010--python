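"""MacKenzie–Bailey goodness-of-fit for single-season occupancy models.

The test compares observed and expected frequencies of complete detection
histories.  Sites are grouped into cohorts sharing the same missingness
pattern; within a cohort every possible history h over the observed
occasions is enumerated, its expected count is the sum over cohort sites of
Pr(h | psi_hat_i, p_hat_i), and the Pearson statistic is

    chi2 = sum_cohorts sum_h (O_h - E_h)^2 / E_h.

Because the statistic's null distribution is unknown for sparse tables, the
p-value comes from a parametric bootstrap: histories are re-simulated from
the fitted model, the model is refitted, and the statistic recomputed.  The
variance-inflation factor c-hat = chi2_obs / mean(chi2_boot) summarises
overdispersion (values near 1 indicate adequate fit; the working rule in
camera-trap studies is p > 0.1 and c-hat < 1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .occupancy import DetectionHistory, FitResult, refit_with_designs, simulate_from_fit

__all__ = ["GofResult", "mb_chisq", "mb_bootstrap"]

_MAX_OCC = 20  # 2^K enumeration bound per cohort
_E_FLOOR = 1e-10


@dataclass
class GofResult:
    chisq_observed: float
    chisq_bootstrap: list[float] = field(default_factory=list)
    p_value: float = float("nan")
    c_hat: float = float("nan")
    n_boot: int = 0
    seed: int = 0
    n_failed: int = 0

    def summary(self) -> dict:
        return {
            "chisq_observed": self.chisq_observed,
            "p_value": self.p_value,
            "c_hat": self.c_hat,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def _cohort_chisq(y_obs: np.ndarray, psi: np.ndarray, p: np.ndarray) -> float:
    """Pearson term for one cohort (all sites share the observed columns).

    ``y_obs``: (n, k) 0/1 histories over the k observed occasions;
    ``p``: (n, k) per-site-occasion detection probabilities.
    """
    n, k = y_obs.shape
    if k > _MAX_OCC:
        raise ValueError(
            f"cohort with {k} observed occasions exceeds the 2^{_MAX_OCC} "
            "enumeration bound; pool occasions before testing"
        )
    hists = ((np.arange(2 ** k)[:, None] >> np.arange(k)[None, :]) & 1).astype(float)  # (H, k)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)  # keeps 0*log(0) finite for boundary fits
    lp = np.log(p)
    l1p = np.log1p(-p)
    # log Pr(h | z=1, site i): (H, n)
    ll_det = hists @ lp.T + (1.0 - hists) @ l1p.T
    pr_given_z1 = np.exp(ll_det)
    all_zero = hists.sum(axis=1) == 0
    pr = psi[None, :] * pr_given_z1 + np.where(all_zero[:, None], (1.0 - psi)[None, :], 0.0)
    expected = pr.sum(axis=1)  # (H,)
    codes = (y_obs.astype(int) * (1 << np.arange(k))[None, :]).sum(axis=1)
    observed = np.bincount(codes, minlength=2 ** k).astype(float)
    keep = expected > _E_FLOOR
    return float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())


def mb_chisq(fit: FitResult, history: DetectionHistory) -> float:
    """Observed MacKenzie–Bailey Pearson chi-square of a fitted model."""
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged model")
    obs = history.observed
    y = np.nan_to_num(history.matrix)
    psi = fit.psi_hat
    p_site = fit.p_hat  # site-level detection (constant across occasions)
    # cohorts = unique missingness patterns
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    chisq = 0.0
    for c in range(patterns.shape[0]):
        sel = inverse == c
        cols = patterns[c]
        if not cols.any():
            continue
        y_c = y[np.ix_(sel, cols)]
        p_c = np.broadcast_to(p_site[sel][:, None], y_c.shape)
        chisq += _cohort_chisq(y_c, psi[sel], np.asarray(p_c))
    return chisq


def mb_bootstrap(fit: FitResult, history: DetectionHistory, n_boot: int = 100,
                 seed: int = 0, n_starts: int = 2) -> GofResult:
    """Parametric-bootstrap p-value and c-hat for the MacKenzie–Bailey test.

    For each bootstrap draw the fitted model generates a new history on the
    template's missingness pattern, the same model specification is
    refitted (warm-started at the original estimates), and the statistic is
    recomputed.  p = (1 + #{chi2_b >= chi2_obs}) / (n_boot + 1), which keeps
    p strictly positive; c-hat = chi2_obs / mean(chi2_b).  Failed refits are
    dropped with a count; more than 20% failures raises a warning.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    chisq_obs = mb_chisq(fit, history)
    rng = np.random.default_rng(seed)
    boots: list[float] = []
    failed = 0
    for b in range(n_boot):
        sim = simulate_from_fit(fit, history, seed=int(rng.integers(0, 2 ** 31 - 1)))
        try:
            refit = refit_with_designs(fit, sim, n_starts=n_starts, seed=b)
        except Exception:
            failed += 1
            continue
        if not refit.converged:
            failed += 1
            continue
        boots.append(mb_chisq(refit, sim))
    if not boots:
        raise RuntimeError("all bootstrap refits failed")
    if failed > 0.2 * n_boot:
        warnings.warn(f"{failed}/{n_boot} bootstrap refits failed", stacklevel=2)
    boots_arr = np.asarray(boots)
    p = (1.0 + float((boots_arr >= chisq_obs).sum())) / (len(boots) + 1.0)
    c_hat = chisq_obs / float(boots_arr.mean())
    return GofResult(chisq_obs, boots, p, c_hat, len(boots), seed, failed)
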