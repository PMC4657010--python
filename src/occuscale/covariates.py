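"""Habitat covariates from a categorical land-cover raster.

Implements the covariate battery used in multi-scale camera-trap habitat
analyses:

* ``majority_resample`` — coarsen the raster grain (pixel size) by assigning
  each new cell the most common class in its source block, as done when
  degrading a 5-m classification to 30/90/250-m grains.
* ``distance_to_class`` — Euclidean distance from a station to the nearest
  cell of a class (D.PLANT, D.WATER), computed per grain.
* ``focal_patch`` — class proportions in a circular focal patch (extent) of
  a given radius around a station.
* ``forest_score`` (FS) — weighted mean of class proportions with integer
  forest-quality weights 0-3.
* ``pielou_evenness`` (HET) — Pielou's evenness of class proportions, a
  land-cover heterogeneity index in [0, 1].
* ``canopy_closure_mean`` (CC) — pooled mean of in-situ densiometer
  transect samples within a cut-off distance of the station.
* ``build_covariate_table`` — the full station x covariate table with the
  column naming D.PLANT_<g>, D.WATER_<g>, FS_<r>, HET_<r>, CC_<d>.

Absent features (e.g. no water cell left after coarsening) yield the
distinguished missing value ``numpy.nan``, never a fabricated distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import LandCoverRaster, ClassInfo, PLANTATION, WATER

logger = logging.getLogger(__name__)

__all__ = [
    "ClassProportions",
    "CovariateTable",
    "majority_resample",
    "distance_to_class",
    "focal_patch",
    "forest_score",
    "pielou_evenness",
    "canopy_closure_mean",
    "build_covariate_table",
]


@dataclass
class ClassProportions:
    """Class proportions inside a focal patch.

    ``coverage`` is the fraction of the ideal (unclipped) disc of cell
    centres that fell inside the raster extent; 1.0 for interior patches.
    """

    proportions: dict[int, float]
    n_pixels: int
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be non-negative")


# ---------------------------------------------------------------------------
# Grain: majority resampling
# ---------------------------------------------------------------------------

def majority_resample(raster: LandCoverRaster, factor: int) -> LandCoverRaster:
    """Coarsen the raster by an integer factor using the majority rule.

    Each output cell takes the modal class of its ``factor x factor`` source
    block; ties go to the smallest class code.  Trailing rows/columns that do
    not fill a block are aggregated over the partial block, preserving the
    full extent.
    """
    if int(factor) != factor or factor <= 0:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return LandCoverRaster(
            raster.grid.copy(), raster.cell_size, raster.origin_x, raster.origin_y,
            dict(raster.legend),
        )
    nr, nc = raster.grid.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    # Pad with a sentinel so partial edge blocks are aggregated, not dropped.
    padded = np.full((out_r * factor, out_c * factor), -1, dtype=raster.grid.dtype)
    padded[:nr, :nc] = raster.grid
    blocks = padded.reshape(out_r, factor, out_c, factor)
    codes = sorted(raster.legend)
    counts = np.empty((len(codes), out_r, out_c), dtype=np.int32)
    for i, code in enumerate(codes):
        counts[i] = (blocks == code).sum(axis=(1, 3))
    # argmax returns the first (= smallest code, since codes sorted) maximum
    winner = np.asarray(codes, dtype=raster.grid.dtype)[counts.argmax(axis=0)]
    # The grid top edge stays anchored; origin_y shifts down if padding grew
    # the nominal extent (the padded rows lie "below" the original extent).
    new_cell = raster.cell_size * factor
    new_origin_y = raster.origin_y + raster.height - out_r * new_cell
    return LandCoverRaster(winner, new_cell, raster.origin_x, new_origin_y, dict(raster.legend))


# ---------------------------------------------------------------------------
# Distance covariates (D.PLANT, D.WATER)
# ---------------------------------------------------------------------------

def distance_to_class(raster: LandCoverRaster, class_codes, x, y):
    """Euclidean distance (m) from point(s) to the nearest cell *centre* of
    the given class(es); 0 if the point's own cell already qualifies.

    Returns ``nan`` (the distinguished absent-feature value) when no cell of
    the class exists in the raster.  Accepts scalar or array coordinates.
    """
    codes = {class_codes} if np.isscalar(class_codes) else set(class_codes)
    if not codes:
        raise ValueError("class_codes must be non-empty")
    scalar = np.isscalar(x)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    ys = np.atleast_1d(np.asarray(y, dtype=float))
    for xi, yi in zip(xs, ys):
        if not raster.contains(xi, yi):
            raise ValueError(f"point ({xi}, {yi}) outside raster extent")
    mask = raster.class_mask(sorted(codes))
    if not mask.any():
        out = np.full(xs.shape, np.nan)
        return float(out[0]) if scalar else out
    rows, cols = np.nonzero(mask)
    cx, cy = raster.cell_center(rows, cols)
    tree = cKDTree(np.column_stack([cx, cy]))
    d, _ = tree.query(np.column_stack([xs, ys]))
    # own-cell rule: a point standing inside a qualifying cell is at distance 0
    for i, (xi, yi) in enumerate(zip(xs, ys)):
        r, c = raster.cell_at(xi, yi)
        if mask[r, c]:
            d[i] = 0.0
    return float(d[0]) if scalar else d


# ---------------------------------------------------------------------------
# Extent: circular focal patches
# ---------------------------------------------------------------------------

def focal_patch(raster: LandCoverRaster, x: float, y: float, radius: float) -> ClassProportions:
    """Class proportions over all cells whose centre lies within ``radius``
    metres of the point.  Cells outside the raster extent are ignored and the
    achieved coverage fraction is reported.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not raster.contains(x, y):
        raise ValueError(f"point ({x}, {y}) outside raster extent")
    cs = raster.cell_size
    # candidate window in cell indices
    r0 = int(np.floor((raster.origin_y + raster.height - (y + radius)) / cs)) - 1
    r1 = int(np.ceil((raster.origin_y + raster.height - (y - radius)) / cs)) + 1
    c0 = int(np.floor(((x - radius) - raster.origin_x) / cs)) - 1
    c1 = int(np.ceil(((x + radius) - raster.origin_x) / cs)) + 1
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cx, cy = raster.cell_center(rows[:, None] * np.ones_like(cols)[None, :],
                                np.ones_like(rows)[:, None] * cols[None, :])
    within = (cx - x) ** 2 + (cy - y) ** 2 <= radius ** 2
    n_ideal = int(within.sum())
    inside = (
        (rows[:, None] >= 0) & (rows[:, None] < raster.n_rows)
        & (cols[None, :] >= 0) & (cols[None, :] < raster.n_cols)
    )
    sel = within & inside
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise ValueError(
            f"no cell centre within {radius} m of ({x}, {y}); use a radius of at "
            f"least ~{cs} m (small patches should contain >= 10 pixels)"
        )
    rr = (rows[:, None] * np.ones_like(cols)[None, :])[sel]
    cc = (np.ones_like(rows)[:, None] * cols[None, :])[sel]
    values = raster.grid[rr.astype(int), cc.astype(int)]
    codes, counts = np.unique(values, return_counts=True)
    props = {int(c): float(n) / n_sel for c, n in zip(codes, counts)}
    coverage = n_sel / n_ideal if n_ideal else 1.0
    if coverage < 1.0:
        logger.info("focal patch at (%.1f, %.1f) r=%g m clipped: coverage %.3f", x, y, radius, coverage)
    return ClassProportions(props, n_sel, coverage)


# ---------------------------------------------------------------------------
# Patch summaries: forest score (FS) and heterogeneity (HET)
# ---------------------------------------------------------------------------

def forest_score(props: ClassProportions, legend: dict[int, ClassInfo]) -> float:
    """Weighted mean of class proportions with forest-quality weights 0-3.

    FS = sum_c weight(c) * proportion(c), hence bounded in [0, 3]: 0 for a
    patch of non-forest classes, 3 for pure dense/primary forest.
    """
    missing = set(props.proportions) - set(legend)
    if missing:
        raise KeyError(f"classes missing from legend: {sorted(missing)}")
    return float(sum(legend[c].forest_weight * p for c, p in props.proportions.items()))


def pielou_evenness(props: ClassProportions) -> float:
    """Pielou's evenness J = H / ln(S): realised Shannon diversity over its
    maximum for the S classes present in the patch.

    J = 0 for a single-class patch (the index is otherwise 0/0 there) and
    J = 1 when all present classes have equal proportions.
    """
    p = np.array([v for v in props.proportions.values() if v > 0.0])
    s = p.size
    if s <= 1:
        return 0.0
    h = float(-(p * np.log(p)).sum())
    return h / np.log(s)


# ---------------------------------------------------------------------------
# In-situ canopy closure (CC)
# ---------------------------------------------------------------------------

def canopy_closure_mean(samples: pd.DataFrame, max_dist: float) -> float:
    """Unweighted mean canopy closure over all transect samples of one
    station with distance-along-transect <= ``max_dist`` metres, pooled
    across transects (a station-point sample at distance 0 is included).

    Returns ``nan`` when no sample lies within range.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    sel = samples.loc[samples["distance"] <= max_dist, "closure"]
    if sel.empty:
        return float("nan")
    return float(sel.mean())


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Station-by-covariate table plus the mean/SD standardization record."""

    data: pd.DataFrame
    means: pd.Series = field(default=None)  # type: ignore[assignment]
    sds: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.means is None:
            self.means = self.data.mean()
        if self.sds is None:
            self.sds = self.data.std(ddof=1)

    def standardized(self, column: str) -> pd.Series:
        sd = self.sds[column]
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant/empty covariate {column!r}")
        return (self.data[column] - self.means[column]) / sd

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="station")


def build_covariate_table(
    raster: LandCoverRaster,
    stations,
    grains=(5, 30, 90, 250),
    radii=(10, 50, 100, 150, 250, 500),
    cc_samples: pd.DataFrame | None = None,
    cc_depths=(50, 100, 150),
    distance_classes: dict[str, int] | None = None,
) -> CovariateTable:
    """Compute the full covariate table for a station set.

    For every grain ``g`` the raster is majority-resampled from its native
    cell size and both distance covariates (``D.PLANT_g``, ``D.WATER_g``)
    are computed; for every radius ``r`` the focal-patch summaries ``FS_r``
    and ``HET_r`` are computed on the native-grain raster; for every depth
    ``d`` the in-situ ``CC_d`` mean is taken from the transect samples
    (``cc_samples`` columns: station, distance, closure).

    Absent features propagate as missing values with a warning.
    """
    if distance_classes is None:
        distance_classes = {"D.PLANT": PLANTATION, "D.WATER": WATER}
    df = stations.df if hasattr(stations, "df") else stations
    ids = df["id"].to_numpy()
    xs = df["x"].to_numpy(float)
    ys = df["y"].to_numpy(float)
    out = pd.DataFrame(index=pd.Index(ids, name="station"))

    for g in grains:
        factor = g / raster.cell_size
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(f"grain {g} is not a multiple of cell size {raster.cell_size}")
        coarse = majority_resample(raster, int(round(factor)))
        for prefix, code in distance_classes.items():
            d = distance_to_class(coarse, code, xs, ys)
            if np.isnan(d).any():
                warnings.warn(
                    f"{prefix} at grain {g}: feature class absent after resampling; "
                    "distances recorded as missing",
                    stacklevel=2,
                )
            out[f"{prefix}_{_fmt(g)}"] = d

    for r in radii:
        fs = np.empty(len(ids))
        het = np.empty(len(ids))
        for i, (x, y) in enumerate(zip(xs, ys)):
            props = focal_patch(raster, x, y, r)
            fs[i] = forest_score(props, raster.legend)
            het[i] = pielou_evenness(props)
        out[f"FS_{_fmt(r)}"] = fs
        out[f"HET_{_fmt(r)}"] = het

    if cc_samples is not None:
        grouped = dict(tuple(cc_samples.groupby("station")))
        for d in cc_depths:
            out[f"CC_{_fmt(d)}"] = [
                canopy_closure_mean(grouped[sid], d) if sid in grouped else np.nan
                for sid in ids
            ]
    return CovariateTable(out)


def _fmt(v) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)
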