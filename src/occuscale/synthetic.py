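"""Synthetic landscapes, camera-trap station layouts and detection histories.

The generator emulates the data-generating conditions of a tropical
production-forest camera-trap study so the whole covariate/occupancy/model-
selection pipeline is testable without field data:

* a 9-class land-cover mosaic at 5-m cells with (i) one large contiguous
  oil-palm plantation block with a near-linear edge, (ii) linear rivers of
  several widths (sub-pixel to multi-pixel at coarse grains) plus small
  ponds, and (iii) a spatially autocorrelated forest-quality mosaic
  (shrub / forest / dense / primary forest) with scattered open patches;
* stations on a jittered systematic grid (~1.4 km spacing, random origin)
  split into three reserve blocks, each station flagged on/off road;
* detection histories drawn from the two-stage occupancy model
  z_i ~ Bern(psi_i), y_ik | z_i ~ Bern(p_ik z_i) with logit-linear psi and
  p, plus independent station-occasion missingness.

Everything is deterministic given its seed; true occupancy states are kept
in the output so parameter/state recovery can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .raster import (
    LandCoverRaster, ClassInfo, DEFAULT_LEGEND,
    BARE, GRASSLAND, PLANTATION, WATER, SHRUB, FOREST, DENSE_FOREST,
    PRIMARY_FOREST, SETTLEMENT,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LandscapeConfig",
    "StationSet",
    "TrueModel",
    "generate_landscape",
    "place_stations",
    "simulate_detection_history",
    "generate_cc_samples",
]


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Parameters of the synthetic land-cover scene.

    Defaults describe an ~18 x 17 km scene at 5-m cells: a plantation block
    covering ~15% of the area, four rivers spanning sub-pixel (5 m) to
    multi-pixel-at-250-m-grain (300 m) widths, 40 small ponds, and a forest
    mosaic autocorrelated at ~200 m.
    """

    width_cells: int = 4200
    height_cells: int = 3400
    cell_size: float = 5.0
    class_legend: dict[int, ClassInfo] = dc_field(default_factory=lambda: dict(DEFAULT_LEGEND))
    plantation_fraction: float = 0.15
    river_widths: tuple[float, ...] = (5.0, 15.0, 60.0, 300.0)
    pond_count: int = 40
    pond_radius_range: tuple[float, float] = (10.0, 60.0)
    forest_mosaic_scale: float = 200.0
    open_patch_fraction: float = 0.04
    settlement_blocks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_cells < 1 or self.height_cells < 1:
            raise ValueError("raster dimensions must be >= 1 cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (0.0 <= self.plantation_fraction < 1.0):
            raise ValueError("plantation_fraction must be in [0, 1)")
        if self.pond_count < 0:
            raise ValueError("pond_count must be non-negative")


@dataclass
class StationSet:
    """Camera-trap stations: id, position (m), reserve, road flag, deployment."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "x", "y", "reserve", "on_road", "deploy_start", "deploy_end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"station table missing columns: {sorted(missing)}")
        if self.df["id"].duplicated().any():
            raise ValueError("station ids must be unique")
        ds = pd.to_datetime(self.df["deploy_start"])
        de = pd.to_datetime(self.df["deploy_end"])
        if (ds > de).any():
            raise ValueError("deploy_start must be <= deploy_end")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path) -> "StationSet":
        df = pd.read_csv(path, parse_dates=["deploy_start", "deploy_end"])
        return cls(df)


@dataclass
class TrueModel:
    """Generating occupancy/detection model for one synthetic species.

    ``psi_slope`` acts per 1 SD of the named occupancy covariate (the
    covariate is z-scored across stations before entering the linear
    predictor, matching how models are fitted).
    """

    psi_intercept: float
    psi_slope: float
    occupancy_covariate: str | None
    p_intercept: float
    p_road: float = 0.0
    p_reserve: dict[str, float] = dc_field(default_factory=dict)
    seed: int = 0
    name: str = "species"

    def __post_init__(self) -> None:
        vals = [self.psi_intercept, self.psi_slope, self.p_intercept, self.p_road,
                *self.p_reserve.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("model coefficients must be finite")


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma_cells) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to zero mean / unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(sigma_cells, 0.5))
    return (f - f.mean()) / (f.std() + 1e-12)


def _fractal_field(rng, shape, sigma_cells, octaves: int = 4, decay: float = 1.0) -> np.ndarray:
    """Multi-octave smoothed noise: structure from the stated scale down to
    eighth-scale with slowly decaying amplitude, as in real land-cover
    mosaics where stand boundaries, gaps and disturbance create patchiness
    at many scales."""
    field = np.zeros(shape)
    weight = 1.0
    for k in range(octaves):
        field += weight * _smooth_field(rng, shape, sigma_cells / 2 ** k)
        weight *= decay
    return (field - field.mean()) / (field.std() + 1e-12)


def generate_landscape(config: LandscapeConfig) -> LandCoverRaster:
    """Generate the synthetic 9-class land-cover raster.

    Layer order (later layers overwrite): forest-quality mosaic, open
    (bare/grassland) patches, settlement blocks, plantation block, water
    (rivers then ponds).  Rivers are rasterized line corridors of the
    requested width; widths below one cell are drawn one cell wide with a
    logged warning.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height_cells, config.width_cells
    cs = config.cell_size
    grid = np.empty((h, w), dtype=np.int16)

    # forest-quality mosaic: thresholded multi-octave noise -> shrub/forest/
    # dense/primary, with patch structure from forest_mosaic_scale down to
    # quarter scale
    base = _fractal_field(rng, (h, w), config.forest_mosaic_scale / cs)
    q = np.quantile(base, [0.15, 0.50, 0.80])
    grid[:] = SHRUB
    grid[base >= q[0]] = FOREST
    grid[base >= q[1]] = DENSE_FOREST
    grid[base >= q[2]] = PRIMARY_FOREST
    # disturbed zone is intrinsically mixed: regrowth shrub interleaved with
    # grass and bare ground at fine scale, so class diversity rises as
    # forest quality falls
    disturbed = base < q[0]
    fine = rng.random((h, w))
    grid[disturbed & (fine < 0.22)] = GRASSLAND
    grid[disturbed & (fine >= 0.78)] = BARE

    # scattered open patches at a finer scale, split bare/grassland.
    # Disturbance clusters in low-quality areas (logged forest: gaps, skid
    # trails and regrowth sit where the canopy is already degraded), which
    # makes land-cover heterogeneity co-vary with forest quality.
    if config.open_patch_fraction > 0:
        open_field = _smooth_field(rng, (h, w), config.forest_mosaic_scale / (2 * cs))
        open_field = (open_field - 0.9 * base) / np.sqrt(1 + 0.81)
        hi = np.quantile(open_field, 1.0 - config.open_patch_fraction)
        mid = np.quantile(open_field, 1.0 - config.open_patch_fraction / 2.0)
        grid[open_field >= hi] = GRASSLAND
        grid[open_field >= mid] = BARE

    # settlement blocks (small rectangles)
    for _ in range(config.settlement_blocks):
        bh, bw = rng.integers(8, 25, size=2)
        r0 = int(rng.integers(0, max(h - bh, 1)))
        c0 = int(rng.integers(0, max(w - bw, 1)))
        grid[r0:r0 + bh, c0:c0 + bw] = SETTLEMENT

    # plantation: left-hand block with a near-linear, slightly noisy edge
    if config.plantation_fraction > 0:
        base_col = config.plantation_fraction * w
        edge_noise = ndimage.gaussian_filter(rng.standard_normal(h), sigma=max(h / 40, 1.0))
        edge_noise = (edge_noise - edge_noise.mean()) / (edge_noise.std() + 1e-12)
        boundary = np.clip(base_col + 3.0 * edge_noise, 0, w).astype(int)
        cols = np.arange(w)[None, :]
        grid[cols < boundary[:, None]] = PLANTATION

    # rivers: horizontal-ish corridors of the stated width
    for width in config.river_widths:
        if width < cs:
            logger.warning("river width %.1f m below one cell (%.1f m); drawing one cell wide",
                           width, cs)
        half_cells = max(width, cs) / (2.0 * cs)
        y0 = rng.uniform(0.15, 0.85) * h
        slope = rng.uniform(-0.1, 0.1)
        amp = rng.uniform(1.0, 4.0) * max(width, cs) / cs
        wavelength = rng.uniform(0.25, 0.5) * w
        xs = np.arange(w)
        center = y0 + slope * (xs - w / 2.0) + amp * np.sin(2 * np.pi * xs / wavelength)
        rows = np.arange(h)[:, None]
        grid[np.abs(rows - center[None, :]) <= half_cells] = WATER

    # ponds: discs with radius drawn from pond_radius_range
    lo, hi_r = config.pond_radius_range
    for _ in range(config.pond_count):
        radius = rng.uniform(lo, hi_r)
        rc = max(radius / cs, 0.5)
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        rr = np.arange(max(int(r0 - rc) - 1, 0), min(int(r0 + rc) + 2, h))
        cc = np.arange(max(int(c0 - rc) - 1, 0), min(int(c0 + rc) + 2, w))
        if rr.size == 0 or cc.size == 0:
            continue
        disc = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2 <= rc ** 2
        sub = grid[np.ix_(rr, cc)]
        sub[disc] = WATER
        grid[np.ix_(rr, cc)] = sub

    return LandCoverRaster(grid, cs, 0.0, 0.0, dict(config.class_legend))


# ---------------------------------------------------------------------------
# Station placement
# ---------------------------------------------------------------------------

def plantation_edge_x(raster: LandCoverRaster, threshold: float = 0.1) -> float:
    """x-coordinate of the right edge of the contiguous plantation band at
    the left of the scene (0 when no left-band plantation exists).  Used to
    keep camera stations inside the forest reserve: surveys sample the
    forest adjacent to plantations, not the plantations themselves."""
    frac = (raster.grid == PLANTATION).mean(axis=0)
    cols = np.nonzero(frac > threshold)[0]
    if cols.size == 0:
        return raster.origin_x
    # last column of the contiguous band starting at the left edge
    end = cols[0]
    for c in cols:
        if c <= end + 2:
            end = c
        else:
            break
    return raster.origin_x + (end + 1) * raster.cell_size


def place_stations(
    raster: LandCoverRaster,
    n_stations: int,
    spacing: float = 1400.0,
    jitter: float = 200.0,
    seed: int = 0,
    road_prob: float = 0.5,
    n_reserves: int = 3,
    start_date: str = "2024-01-01",
    duration_days: int = 42,
    reserve_stagger_days: int = 120,
    x_min: float | None = None,
) -> StationSet:
    """Stations on a systematic grid with random origin plus radial jitter.

    The jitter displacement is uniform in a disc of the given radius, so
    every nearest-neighbour distance lies in [spacing - 2*jitter,
    spacing + 2*jitter].  Reserve labels split the grid into ``n_reserves``
    vertical (x-axis) blocks; each reserve deploys for ``duration_days``
    starting ``reserve_stagger_days`` apart.  On-road flags are i.i.d.
    Bernoulli(road_prob).  ``x_min`` restricts the grid to x >= x_min
    (e.g. the plantation edge from :func:`plantation_edge_x`).
    """
    rng = np.random.default_rng(seed)
    margin = jitter + raster.cell_size
    x_low = max(raster.origin_x, x_min if x_min is not None else raster.origin_x)
    avail_w = (raster.origin_x + raster.width) - x_low - 2 * margin
    avail_h = raster.height - 2 * margin
    ncols = int(avail_w // spacing) + 1 if avail_w >= 0 else 0
    nrows = int(avail_h // spacing) + 1 if avail_h >= 0 else 0
    if ncols * nrows < n_stations:
        need_cols = int(np.ceil(np.sqrt(n_stations)))
        need_w = (need_cols - 1) * spacing + 2 * margin
        raise ValueError(
            f"raster {raster.width:.0f} x {raster.height:.0f} m fits only "
            f"{ncols * nrows} stations at spacing {spacing} m (need {n_stations}; "
            f"a square layout needs >= {need_w:.0f} m per side)"
        )
    # shrink to the tightest grid that still holds n_stations
    while (ncols - 1) * nrows >= n_stations:
        ncols -= 1
    while ncols * (nrows - 1) >= n_stations:
        nrows -= 1
    span_x = (ncols - 1) * spacing
    span_y = (nrows - 1) * spacing
    ox = x_low + margin + rng.uniform(0, max(avail_w - span_x, 0))
    oy = raster.origin_y + margin + rng.uniform(0, max(avail_h - span_y, 0))

    gx, gy = np.meshgrid(np.arange(ncols), np.arange(nrows))
    gx = gx.ravel()[:n_stations]
    gy = gy.ravel()[:n_stations]
    if jitter > 0:
        theta = rng.uniform(0, 2 * np.pi, n_stations)
        rad = jitter * np.sqrt(rng.uniform(0, 1, n_stations))
        dx, dy = rad * np.cos(theta), rad * np.sin(theta)
    else:
        dx = dy = np.zeros(n_stations)
    xs = ox + gx * spacing + dx
    ys = oy + gy * spacing + dy

    reserve_idx = np.minimum((gx * n_reserves) // max(ncols, 1), n_reserves - 1)
    labels = [chr(ord("A") + int(i)) for i in reserve_idx]
    t0 = pd.Timestamp(start_date)
    starts = [t0 + pd.Timedelta(days=int(i) * reserve_stagger_days) for i in reserve_idx]
    df = pd.DataFrame({
        "id": [f"st{i + 1:03d}" for i in range(n_stations)],
        "x": xs,
        "y": ys,
        "reserve": labels,
        "on_road": rng.random(n_stations) < road_prob,
        "deploy_start": starts,
        "deploy_end": [s + pd.Timedelta(days=duration_days - 1) for s in starts],
    })
    return StationSet(df)


# ---------------------------------------------------------------------------
# Detection-history simulation
# ---------------------------------------------------------------------------

def simulate_detection_history(
    stations: StationSet,
    covariates,
    truth: TrueModel,
    n_occasions: int = 7,
    missing_rate: float = 0.1,
):
    """Draw a detection history from the two-stage occupancy model.

    z_i ~ Bernoulli(psi_i) with logit(psi_i) = beta0 + beta1 * x_i where x
    is the z-scored occupancy covariate; y_ik | z_i ~ Bernoulli(p_ik z_i)
    with logit(p_ik) = gamma0 + gamma_road * road_i + reserve offset.  Each
    station-occasion is then masked missing independently with probability
    ``missing_rate``.  True z values are kept on the result for recovery
    tests.  Deterministic given ``truth.seed``.
    """
    from .occupancy import DetectionHistory

    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(truth.seed)
    df = stations.df
    n = len(df)

    if truth.occupancy_covariate is None:
        eta = np.full(n, truth.psi_intercept)
    else:
        cdf = covariates.data if hasattr(covariates, "data") else covariates
        if truth.occupancy_covariate not in cdf.columns:
            raise KeyError(f"unknown occupancy covariate {truth.occupancy_covariate!r}")
        x = cdf[truth.occupancy_covariate].reindex(df["id"]).to_numpy(float)
        if np.isnan(x).any():
            bad = df["id"].to_numpy()[np.isnan(x)]
            raise ValueError(
                f"missing covariate {truth.occupancy_covariate!r} at station(s) {bad[:5].tolist()}"
            )
        sd = x.std(ddof=1)
        xz = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        eta = truth.psi_intercept + truth.psi_slope * xz
    psi = expit(eta)

    gp = np.full(n, truth.p_intercept)
    gp += truth.p_road * df["on_road"].to_numpy(float)
    if truth.p_reserve:
        gp += df["reserve"].map(lambda r: truth.p_reserve.get(r, 0.0)).to_numpy(float)
    p = expit(gp)

    z = rng.random(n) < psi
    y = (rng.random((n, n_occasions)) < (p[:, None] * z[:, None])).astype(float)
    if missing_rate > 0:
        y[rng.random((n, n_occasions)) < missing_rate] = np.nan
    return DetectionHistory(df["id"].tolist(), y, true_z=z.astype(float))


# ---------------------------------------------------------------------------
# In-situ canopy-closure transects
# ---------------------------------------------------------------------------

def generate_cc_samples(
    raster: LandCoverRaster,
    stations: StationSet,
    seed: int = 0,
    step: float = 50.0,
    transect_length: float = 250.0,
    bearings=(0.0, 120.0, 240.0),
    canopy_scale: float = 60.0,
    canopy_sd: float = 0.25,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Densiometer-style canopy-closure samples along 3 transects per station.

    Samples every ``step`` m (including the station point at 0 m) along
    transects at the given bearings.  Closure at a point is the local
    forest-quality weight (weight/3 scaled into [0.1, 0.9]) plus a smooth
    canopy deviation field (spatial scale ``canopy_scale`` m, SD
    ``canopy_sd``) plus small reading noise, clipped to [0, 1].  Canopy
    closure is thus a distinct vegetation-structure variable that co-varies
    with, but is not a deterministic function of, the land-cover class.
    Points falling outside the raster are skipped (emulating transects cut
    short in the field).
    """
    rng = np.random.default_rng(seed)
    rows = []
    dists = np.arange(0.0, transect_length + 1e-9, step)
    wgrid = raster.weights_grid()
    canopy_dev = canopy_sd * _smooth_field(rng, raster.grid.shape,
                                           canopy_scale / raster.cell_size)
    for st in stations.df.itertuples():
        for b_i, bearing in enumerate(bearings):
            rad = np.deg2rad(bearing)
            for d in dists:
                if b_i > 0 and d == 0.0:
                    continue  # station point sampled once
                x = st.x + d * np.sin(rad)
                y = st.y + d * np.cos(rad)
                if not raster.contains(x, y):
                    continue
                r, c = raster.cell_at(x, y)
                base = 0.1 + 0.8 * (wgrid[r, c] / 3.0) + canopy_dev[r, c]
                closure = float(np.clip(base + rng.normal(0.0, noise_sd), 0.0, 1.0))
                rows.append((st.id, bearing, d, closure))
    return pd.DataFrame(rows, columns=["station", "bearing", "distance", "closure"])
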