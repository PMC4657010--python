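import numpy as np
import pandas as pd
import pytest

import occuscale as oc


@pytest.fixture
def tiny_raster():
    """6x6 single-class forest raster at 5-m cells."""
    grid = np.full((6, 6), 6, dtype=np.int64)  # forest
    return oc.LandCoverRaster(grid, cell_size=5.0)


def make_station_table(n, rng, reserves=("A", "B", "C"), n_occ_days=42):
    return oc.StationSet(pd.DataFrame({
        "id": [f"s{i:03d}" for i in range(n)],
        "x": rng.uniform(0, 1000, n),
        "y": rng.uniform(0, 1000, n),
        "reserve": rng.choice(list(reserves), n),
        "on_road": rng.random(n) < 0.5,
        "deploy_start": pd.Timestamp("2024-01-01"),
        "deploy_end": pd.Timestamp("2024-01-01") + pd.Timedelta(days=n_occ_days - 1),
    }))


@pytest.fixture
def stations150():
    return make_station_table(150, np.random.default_rng(42))


def study_landscape(seed: int, with_cc: bool = True):
    """One synthetic study replicate: landscape, 150 stations at 1.4-km
    spacing, and the full multi-grain/multi-radius covariate table.

    Shared across the simulation studies so each landscape is generated
    once; detection histories are then drawn repeatedly on top.
    """
    from occuscale.synthetic import plantation_edge_x

    cfg = oc.LandscapeConfig(seed=seed)
    raster = oc.generate_landscape(cfg)
    stations = oc.place_stations(raster, 150, spacing=1400.0, jitter=200.0, seed=seed + 1,
                                 x_min=plantation_edge_x(raster) + 100.0)
    cc = oc.generate_cc_samples(raster, stations, seed=seed + 2) if with_cc else None
    covtab = oc.build_covariate_table(
        raster, stations, grains=(5, 30, 90, 250), radii=(10, 50, 100, 150, 250, 500),
        cc_samples=cc, cc_depths=(50, 100, 150),
    )
    return stations, covtab


@pytest.fixture(scope="session")
def study_replicates():
    """Ten independent study landscapes with stations and covariates."""
    return [study_landscape(1000 + 10 * k) for k in range(10)]
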