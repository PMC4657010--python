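"""Categorical land-cover raster container and ESRI ASCII grid I/O.

The raster is a dense integer grid of land-cover class codes with square
cells, stored row-major with row 0 at the *top* (north) edge, together with
a legend mapping each class code to a name and an integer forest-quality
weight in {0, 1, 2, 3}.  The weights encode the field scheme used for the
forest score: bare ground, grassland, oil-palm plantation and water carry
weight 0, shrub 1, (logged) forest 2, dense and primary forest 3.

Geometry convention: ``origin_x``/``origin_y`` are the coordinates of the
lower-left corner of the grid (the ESRI ASCII ``xllcorner``/``yllcorner``).
The centre of cell ``(row, col)`` is at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y + (n_rows - row - 0.5) * cell_size
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ClassInfo",
    "DEFAULT_LEGEND",
    "LandCoverRaster",
    "read_ascii_grid",
    "write_ascii_grid",
    "WATER",
    "PLANTATION",
]

# Default 9-class legend. Codes are arbitrary but fixed; weights follow the
# forest-quality ranking (0 = non-forest, 3 = dense/primary forest).
BARE, GRASSLAND, PLANTATION, WATER = 1, 2, 3, 4
SHRUB, FOREST, DENSE_FOREST, PRIMARY_FOREST = 5, 6, 7, 8
SETTLEMENT = 9


@dataclass(frozen=True)
class ClassInfo:
    name: str
    forest_weight: int

    def __post_init__(self) -> None:
        if self.forest_weight not in (0, 1, 2, 3):
            raise ValueError(f"forest_weight must be in {{0,1,2,3}}, got {self.forest_weight}")


DEFAULT_LEGEND: dict[int, ClassInfo] = {
    BARE: ClassInfo("bare", 0),
    GRASSLAND: ClassInfo("grassland", 0),
    PLANTATION: ClassInfo("oil_palm_plantation", 0),
    WATER: ClassInfo("water", 0),
    SHRUB: ClassInfo("shrub", 1),
    FOREST: ClassInfo("forest", 2),
    DENSE_FOREST: ClassInfo("dense_forest", 3),
    PRIMARY_FOREST: ClassInfo("primary_forest", 3),
    SETTLEMENT: ClassInfo("settlement", 0),
}

_NODATA = -9999


@dataclass
class LandCoverRaster:
    """Integer class-code grid with square cells and a class legend."""

    grid: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    legend: dict[int, ClassInfo] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer class codes")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        present = set(np.unique(self.grid).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"grid contains codes missing from legend: {sorted(unknown)}")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def width(self) -> float:
        """Extent in metres along x."""
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x <= self.origin_x + self.width
            and self.origin_y <= y <= self.origin_y + self.height
        )

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y)."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        col = min(int((x - self.origin_x) / self.cell_size), self.n_cols - 1)
        row = min(int((self.origin_y + self.height - y) / self.cell_size), self.n_rows - 1)
        return row, col

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def class_mask(self, class_codes) -> np.ndarray:
        codes = {class_codes} if np.isscalar(class_codes) else set(class_codes)
        return np.isin(self.grid, sorted(codes))

    def class_fraction(self, class_codes) -> float:
        return float(self.class_mask(class_codes).mean())

    def weights_grid(self) -> np.ndarray:
        """Forest-quality weight of every cell."""
        lut = np.zeros(max(self.legend) + 1, dtype=np.int8)
        for code, info in self.legend.items():
            lut[code] = info.forest_weight
        return lut[self.grid]


# -- ESRI ASCII grid I/O (bit-exact round trip for integer grids) ---------

def write_ascii_grid(raster: LandCoverRaster, path: str | Path) -> None:
    path = Path(path)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x:.6f}\n"
        f"yllcorner {raster.origin_y:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_ascii_grid(path: str | Path, legend: dict[int, ClassInfo] | None = None) -> LandCoverRaster:
    """Read an ESRI ASCII grid.

    The format does not carry a class legend; pass one or the default
    9-class legend is assumed.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and not _is_number(parts[0]):
                meta[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    return LandCoverRaster(
        grid=grid,
        cell_size=meta.get("cellsize", 1.0),
        origin_x=meta.get("xllcorner", 0.0),
        origin_y=meta.get("yllcorner", 0.0),
        legend=dict(legend) if legend is not None else dict(DEFAULT_LEGEND),
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
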