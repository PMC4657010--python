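"""Two-stage AIC model selection across spatial grains and extents.

Stage one selects the detection model: the four candidates p(1), p(road),
p(reserve), p(road+reserve) are fitted with occupancy held constant, and
the AIC-best (the "constant occupancy model") fixes the detection terms for
everything downstream.  Stage two compares single-occupancy-covariate
models of the same covariate computed at several scales (grains or focal
radii) against each other and the constant model, reporting AIC, dAIC,
Akaike weights and Wald inference per row.  Finally the consensus radius
aggregates dAIC across species: for each radius the dAIC values (each
computed within that species' own candidate set, constant model included)
are summed over species and covariates, and the consensus radius minimises
the total over the radii available for every covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import DetectionHistory, FitResult, ModelSpec, fit_occupancy, wald_inference

__all__ = [
    "akaike_weights",
    "select_detection_model",
    "scale_comparison",
    "cumulative_delta_aic",
    "ConsensusResult",
    "CONSTANT_LABEL",
]

CONSTANT_LABEL = "—"
_TIE_TOL = 1e-6


def akaike_weights(aics) -> np.ndarray:
    """Akaike model weights w_m = exp(-d_m/2) / sum_j exp(-d_j/2) with
    d_m = AIC_m - min AIC.  Non-finite AICs (non-converged models) get
    weight 0 and are excluded from the normalisation."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("need at least one AIC value")
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("no finite AIC values")
    w = np.zeros_like(aics)
    d = aics[finite] - aics[finite].min()
    ew = np.exp(-d / 2.0)
    w[finite] = ew / ew.sum()
    return w


def select_detection_model(history: DetectionHistory, stations, seed: int = 0,
                           n_starts: int = 5) -> FitResult:
    """Fit the four detection candidates under constant occupancy and return
    the AIC-best; AIC ties (< 1e-6) go to the model with fewer parameters."""
    candidates = [(), ("road",), ("reserve",), ("road", "reserve")]
    fits: list[FitResult] = []
    for i, terms in enumerate(candidates):
        spec = ModelSpec(psi_terms=(), p_terms=terms)
        try:
            fit = fit_occupancy(history, spec, stations=stations, seed=seed + i,
                                n_starts=n_starts)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"detection candidate {spec.label()} failed: {exc}", stacklevel=2)
            continue
        if not fit.converged:
            warnings.warn(f"detection candidate {spec.label()} did not converge; excluded",
                          stacklevel=2)
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("no detection model converged")
    # among fits within tolerance of the minimum AIC, fewest parameters wins
    amin = min(f.AIC for f in fits)
    tied = [f for f in fits if f.AIC - amin < _TIE_TOL]
    return min(tied, key=lambda f: f.K)


def scale_comparison(
    history: DetectionHistory,
    variants: dict,
    p_terms: tuple[str, ...],
    covariates,
    stations=None,
    seed: int = 0,
    n_starts: int = 5,
) -> pd.DataFrame:
    """AIC table over scale variants of one covariate.

    ``variants`` maps a scale label (e.g. radius or grain in metres) to the
    covariate column for that scale.  One single-covariate model per variant
    is fitted with the fixed best detection terms, plus the constant-
    occupancy model (labelled "—").  Returns the ranked table with columns
    model, AIC, dAIC, wAIC, beta1, SE, CV, p_value, converged; the constant
    row carries no slope inference, and non-converged variants are retained
    with missing inference fields but excluded from the weights.
    """
    if not variants:
        raise ValueError("need at least one scale variant")
    rows = []
    for j, (label, column) in enumerate(variants.items()):
        spec = ModelSpec(psi_terms=(column,), p_terms=tuple(p_terms))
        fit = fit_occupancy(history, spec, covariates=covariates, stations=stations,
                            seed=seed + j, n_starts=n_starts)
        if fit.converged:
            wi = wald_inference(fit)
            slope = wi.iloc[1]  # first occupancy covariate row
            rows.append((str(label), fit.AIC, slope["estimate"], slope["SE"],
                         slope["CV"], slope["p_value"], True))
        else:
            warnings.warn(f"variant {label} did not converge; inference omitted", stacklevel=2)
            rows.append((str(label), np.nan, np.nan, np.nan, np.nan, np.nan, False))
    const_spec = ModelSpec(psi_terms=(), p_terms=tuple(p_terms))
    const_fit = fit_occupancy(history, const_spec, stations=stations, seed=seed + 97,
                              n_starts=n_starts)
    rows.append((CONSTANT_LABEL, const_fit.AIC if const_fit.converged else np.nan,
                 np.nan, np.nan, np.nan, np.nan, const_fit.converged))

    table = pd.DataFrame(rows, columns=["model", "AIC", "beta1", "SE", "CV",
                                        "p_value", "converged"])
    table["dAIC"] = table["AIC"] - np.nanmin(table["AIC"].to_numpy())
    table["wAIC"] = akaike_weights(table["AIC"].to_numpy())
    table = table.sort_values("AIC", na_position="last", kind="mergesort").reset_index(drop=True)
    return table[["model", "AIC", "dAIC", "wAIC", "beta1", "SE", "CV", "p_value", "converged"]]


@dataclass
class ConsensusResult:
    """Cumulative dAIC per (covariate, radius) and the consensus radius."""

    cumulative: pd.DataFrame  # index: radius, columns: covariates (NaN = unavailable)
    common_radii: list
    consensus_radius: float

    def to_csv(self, path) -> None:
        out = self.cumulative.copy()
        out.index.name = "radius"
        out.to_csv(path, na_rep=CONSTANT_LABEL, float_format="%.2f")


def cumulative_delta_aic(tables: dict, radii) -> ConsensusResult:
    """Consensus radius from per-species AIC tables.

    ``tables``: {covariate name: {species: AIC table from scale_comparison}}
    with radius labels as the ``model`` column.  For each covariate and
    radius, that radius's dAIC (within each species' own candidate set,
    constant model included) is summed across species.  The consensus radius
    minimises the total over covariates, restricted to radii available for
    every covariate; ties go to the smaller radius.
    """
    radii = list(radii)
    cum: dict[str, dict[float, float]] = {}
    for cov, per_species in tables.items():
        # radii this covariate offers = union over species (minus constant row)
        offered = set()
        for t in per_species.values():
            offered |= {float(m) for m in t["model"] if m != CONSTANT_LABEL}
        avail = [r for r in radii if float(r) in offered]
        cum[cov] = {}
        for r in avail:
            total = 0.0
            for sp, t in per_species.items():
                row = t.loc[t["model"] == str(r)]
                if row.empty:
                    raise KeyError(f"radius {r} missing for species {sp!r} (covariate {cov!r})")
                total += float(row["dAIC"].iloc[0])
            cum[cov][float(r)] = total

    cdf = pd.DataFrame(cum).reindex([float(r) for r in radii])
    common = [r for r in radii if not cdf.loc[float(r)].isna().any()]
    if not common:
        raise ValueError("no radius is available for all covariates")
    totals = cdf.loc[[float(r) for r in common]].sum(axis=1)
    # stable argmin with smaller-radius tie rule (index already ascending)
    consensus = float(totals.idxmin())
    return ConsensusResult(cdf, common, consensus)
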