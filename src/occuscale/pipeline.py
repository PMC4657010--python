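"""End-to-end experiment orchestration.

Runs the full scale-sensitivity experiment from one config: synthesize a
landscape, place stations, derive the covariate table at all grains and
radii, simulate per-species detection histories, then

* goal 1 — AIC tables for the distance covariates (D.PLANT, D.WATER)
  computed at each grain (pixel resolution);
* goal 2 — AIC tables for FS/HET over the focal radii and CC over the
  in-situ depths, plus the cumulative-dAIC consensus radius;
* gof — MacKenzie–Bailey parametric bootstrap for each species' global
  model (best detection terms + the consensus-radius forest score).

All stage seeds derive from the master seed by hashing the stage name, so
stages are reproducible independently of execution order.  Outputs are CSV
tables plus a JSON run manifest; an existing output directory is never
overwritten without ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import build_covariate_table, CovariateTable
from .gof import mb_bootstrap
from .occupancy import ModelSpec, fit_occupancy
from .selection import (
    CONSTANT_LABEL, cumulative_delta_aic, scale_comparison, select_detection_model,
)
from .synthetic import (
    LandscapeConfig, StationSet, TrueModel, generate_cc_samples,
    generate_landscape, place_stations, plantation_edge_x,
    simulate_detection_history,
)
from .raster import write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "stage_seed", "default_species", "Experiment"]

_TABLE_DECIMALS = {"AIC": 2, "dAIC": 2, "wAIC": 3, "beta1": 2, "SE": 2,
                   "CV": 2, "p_value": 4}


def _format_table(table: pd.DataFrame) -> pd.DataFrame:
    return table.drop(columns="converged").round(_TABLE_DECIMALS)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of (master seed, stage name),
    truncated below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def default_species(seed: int = 0) -> list[TrueModel]:
    """Six synthetic species spanning the covariate associations the study
    design probes: water at fine/coarse grain, forest score, heterogeneity,
    canopy closure, and plantation edge."""
    p0 = float(np.log(0.35 / 0.65))  # baseline per-occasion detection ~0.35
    specs = [
        ("water_fine", -2.0, "D.WATER_5", {"p_road": 0.8}),
        ("water_coarse", -1.2, "D.WATER_90", {}),
        ("forest_50", 1.5, "FS_50", {"p_road": -0.5}),
        ("hetero_50", 1.2, "HET_50", {}),
        ("canopy_50", 1.2, "CC_50", {"p_reserve": {"B": 0.4, "C": -0.4}}),
        ("plantation_edge", 1.0, "D.PLANT_5", {}),
    ]
    return [
        TrueModel(psi_intercept=0.0, psi_slope=slope, occupancy_covariate=cov,
                  p_intercept=p0, seed=stage_seed(seed, f"species:{name}"), name=name,
                  **extras)
        for name, slope, cov, extras in specs
    ]


@dataclass
class ExperimentConfig:
    """Full experiment configuration (one synthetic study)."""

    landscape: LandscapeConfig = dc_field(default_factory=LandscapeConfig)
    n_stations: int = 150
    spacing: float = 1400.0
    jitter: float = 200.0
    truths: list[TrueModel] = dc_field(default_factory=list)
    grains: tuple[float, ...] = (5, 30, 90, 250)
    radii: tuple[float, ...] = (10, 50, 100, 150, 250, 500)
    cc_depths: tuple[float, ...] = (50, 100, 150)
    occasion_length: int = 6
    n_occasions: int = 7
    missing_rate: float = 0.1  # camera-failure rate: a guess, the field value is unreported
    n_boot: int = 100
    master_seed: int = 1
    output_dir: str = "occuscale_out"

    def __post_init__(self) -> None:
        for g in self.grains:
            if abs(g / self.landscape.cell_size - round(g / self.landscape.cell_size)) > 1e-9:
                raise ValueError(f"grain {g} not a multiple of cell size {self.landscape.cell_size}")
        if list(self.radii) != sorted(self.radii) or min(self.radii) <= 0:
            raise ValueError("radii must be positive and ascending")
        if not self.truths:
            self.truths = default_species(self.master_seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        landscape = LandscapeConfig(**raw.pop("landscape", {}))
        truths = [TrueModel(**t) for t in raw.pop("truths", [])]
        for key in ("grains", "radii", "cc_depths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(landscape=landscape, truths=truths, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["landscape"]["class_legend"] = {
            code: [info.name, info.forest_weight]
            for code, info in self.landscape.class_legend.items()
        }
        return d


class Experiment:
    """Stateful runner over one config: stages reuse shared intermediates."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.raster = None
        self.stations: StationSet | None = None
        self.covariates: CovariateTable | None = None
        self.cc_samples: pd.DataFrame | None = None
        self.histories: dict[str, object] = {}
        self.detection_fits: dict[str, object] = {}
        self.goal2_tables: dict[str, dict[str, pd.DataFrame]] = {}
        self.consensus = None
        self.manifest: dict = {
            "package_version": __version__,
            "master_seed": config.master_seed,
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seeds": {},
            "timings_s": {},
            "outputs": [],
            "warnings": [],
        }

    # -- shared stages ----------------------------------------------------

    def simulate(self, outdir: Path | None = None):
        """Landscape, stations, covariate table and canopy transects."""
        cfg = self.config
        t0 = time.perf_counter()
        lseed = stage_seed(cfg.master_seed, "landscape")
        sseed = stage_seed(cfg.master_seed, "stations")
        cseed = stage_seed(cfg.master_seed, "cc_samples")
        self.manifest["seeds"].update(landscape=lseed, stations=sseed, cc_samples=cseed)
        land_cfg = LandscapeConfig(**{**asdict(cfg.landscape), "class_legend": cfg.landscape.class_legend, "seed": lseed})
        self.raster = generate_landscape(land_cfg)
        # stations sample the forest reserve, not the plantation block
        edge = plantation_edge_x(self.raster)
        self.stations = place_stations(
            self.raster, cfg.n_stations, cfg.spacing, cfg.jitter, seed=sseed,
            duration_days=cfg.n_occasions * cfg.occasion_length,
            x_min=edge + 100.0 if edge > self.raster.origin_x else None,
        )
        self.cc_samples = generate_cc_samples(self.raster, self.stations, seed=cseed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            self.covariates = build_covariate_table(
                self.raster, self.stations, cfg.grains, cfg.radii,
                self.cc_samples, cfg.cc_depths,
            )
        self.manifest["warnings"] += [str(w.message) for w in caught]
        self.manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 2)
        if outdir is not None:
            self._write(outdir, "landscape.asc", lambda p: write_ascii_grid(self.raster, p))
            self._write(outdir, "stations.csv", self.stations.to_csv)
            self._write(outdir, "covariates.csv", self.covariates.to_csv)
            self._write(outdir, "cc_samples.csv",
                        lambda p: self.cc_samples.to_csv(p, index=False))
        return self

    def _require_simulated(self):
        if self.covariates is None:
            self.simulate()

    def _history(self, truth: TrueModel):
        if truth.name not in self.histories:
            self.histories[truth.name] = simulate_detection_history(
                self.stations, self.covariates, truth,
                n_occasions=self.config.n_occasions,
                missing_rate=self.config.missing_rate,
            )
        return self.histories[truth.name]

    def _best_p(self, truth: TrueModel):
        if truth.name not in self.detection_fits:
            hist = self._history(truth)
            self.detection_fits[truth.name] = select_detection_model(
                hist, self.stations, seed=stage_seed(self.config.master_seed, f"p:{truth.name}"),
            )
        return self.detection_fits[truth.name]

    # -- goals ------------------------------------------------------------

    def run_goal1(self, outdir: Path | None = None) -> dict:
        """Distance covariates across grains: one AIC table per species per
        covariate (D.PLANT, D.WATER)."""
        self._require_simulated()
        cfg = self.config
        t0 = time.perf_counter()
        results: dict[str, dict[str, pd.DataFrame]] = {}
        for truth in cfg.truths:
            hist = self._history(truth)
            best_p = self._best_p(truth).spec.p_terms
            results[truth.name] = {}
            for cov in ("D.PLANT", "D.WATER"):
                variants = {int(g): f"{cov}_{int(g)}" for g in cfg.grains}
                table = scale_comparison(
                    hist, variants, best_p, self.covariates, self.stations,
                    seed=stage_seed(cfg.master_seed, f"goal1:{truth.name}:{cov}"),
                )
                results[truth.name][cov] = table
                if outdir is not None:
                    name = f"goal1_{truth.name}_{cov.replace('.', '')}.csv"
                    self._write(outdir, name, lambda p, t=table: _format_table(t).to_csv(p, index=False, na_rep=CONSTANT_LABEL))
        self.manifest["timings_s"]["goal1"] = round(time.perf_counter() - t0, 2)
        return results

    def run_goal2(self, outdir: Path | None = None):
        """Focal-patch covariates across radii plus the consensus radius."""
        self._require_simulated()
        cfg = self.config
        t0 = time.perf_counter()
        families = {
            "FS": [int(r) for r in cfg.radii],
            "HET": [int(r) for r in cfg.radii],
            "CC": [int(d) for d in cfg.cc_depths],
        }
        tables: dict[str, dict[str, pd.DataFrame]] = {c: {} for c in families}
        for truth in cfg.truths:
            hist = self._history(truth)
            best_p = self._best_p(truth).spec.p_terms
            for cov, scales in families.items():
                variants = {s: f"{cov}_{s}" for s in scales}
                table = scale_comparison(
                    hist, variants, best_p, self.covariates, self.stations,
                    seed=stage_seed(cfg.master_seed, f"goal2:{truth.name}:{cov}"),
                )
                tables[cov][truth.name] = table
                if outdir is not None:
                    self._write(outdir, f"goal2_{truth.name}_{cov}.csv",
                                lambda p, t=table: _format_table(t).to_csv(p, index=False, na_rep=CONSTANT_LABEL))
        self.goal2_tables = tables
        self.consensus = cumulative_delta_aic(tables, [int(r) for r in cfg.radii])
        self.manifest["consensus_radius_m"] = self.consensus.consensus_radius
        if outdir is not None:
            self._write(outdir, "goal2_cumulative_dAIC.csv", self.consensus.to_csv)
        self.manifest["timings_s"]["goal2"] = round(time.perf_counter() - t0, 2)
        return tables, self.consensus

    def run_gof(self, outdir: Path | None = None) -> pd.DataFrame:
        """MacKenzie–Bailey bootstrap per species on the global model
        (best detection terms + consensus-radius forest score)."""
        self._require_simulated()
        if self.consensus is None:
            self.run_goal2(outdir)
        cfg = self.config
        t0 = time.perf_counter()
        radius = int(self.consensus.consensus_radius)
        rows = []
        for truth in cfg.truths:
            hist = self._history(truth)
            best_p = self._best_p(truth).spec.p_terms
            spec = ModelSpec(psi_terms=(f"FS_{radius}",), p_terms=best_p)
            fit = fit_occupancy(hist, spec, covariates=self.covariates,
                                stations=self.stations,
                                seed=stage_seed(cfg.master_seed, f"gof_fit:{truth.name}"))
            if not fit.converged:
                warnings.warn(f"global model for {truth.name} did not converge; GOF skipped",
                              stacklevel=2)
                rows.append((truth.name, np.nan, np.nan, np.nan, 0, False))
                continue
            gof = mb_bootstrap(fit, hist, n_boot=cfg.n_boot,
                               seed=stage_seed(cfg.master_seed, f"gof:{truth.name}"))
            rows.append((truth.name, gof.chisq_observed, gof.p_value, gof.c_hat,
                         gof.n_boot, True))
        out = pd.DataFrame(rows, columns=["species", "chisq", "p_value", "c_hat",
                                          "n_boot", "converged"])
        if outdir is not None:
            rounded = out.round({"chisq": 2, "p_value": 3, "c_hat": 3})
            self._write(outdir, "gof_summary.csv", lambda p: rounded.to_csv(p, index=False))
        self.manifest["timings_s"]["gof"] = round(time.perf_counter() - t0, 2)
        return out

    def run_all(self, outdir: str | Path | None = None, force: bool = False):
        outdir = self._prepare_outdir(outdir, force)
        self.simulate(outdir)
        self.run_goal1(outdir)
        self.run_goal2(outdir)
        self.run_gof(outdir)
        self.write_manifest(outdir)
        return self

    # -- bookkeeping -------------------------------------------------------

    def _prepare_outdir(self, outdir, force: bool) -> Path:
        outdir = Path(outdir if outdir is not None else self.config.output_dir)
        if outdir.exists() and any(outdir.iterdir()) and not force:
            raise FileExistsError(
                f"output directory {outdir} is not empty; pass force=True/--force to overwrite"
            )
        outdir.mkdir(parents=True, exist_ok=True)
        return outdir

    def _write(self, outdir: Path, name: str, writer) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / name
        writer(path)
        self.manifest["outputs"].append(name)

    def write_manifest(self, outdir) -> None:
        self._write(Path(outdir), "manifest.json",
                    lambda p: Path(p).write_text(json.dumps(self.manifest, indent=2, default=str)))
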