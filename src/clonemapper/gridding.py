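"""Tile grid, spot rasterization and the cell-density field.

Signals are aggregated over square tiles (default 100 × 100 µm) before
modelling; the per-tile nucleus count doubles as the model's exposure term and,
converted to cells/mm², as the rendering mask. Tiles are half-open squares
[x0, x0+Δ) × [y0, y0+Δ), so a point on a shared edge belongs to the
higher-index tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import CellTable, ProbePanel, SpotTable, ValidationError

DEFAULT_TILE_SIZE = 100.0  # µm


@dataclass(frozen=True)
class Grid:
    origin: tuple[float, float]
    tile_size: float
    nx: int
    ny: int

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    def tile_indices(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat tile index (iy * nx + ix) per point; -1 when out of bounds."""
        ix = np.floor((np.asarray(x, float) - self.origin[0]) / self.tile_size).astype(int)
        iy = np.floor((np.asarray(y, float) - self.origin[1]) / self.tile_size).astype(int)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        flat = iy * self.nx + ix
        flat[~ok] = -1
        return flat

    def tile_centres(self) -> np.ndarray:
        """(n_tiles, 2) array of tile centre coordinates in µm."""
        xs = self.origin[0] + (np.arange(self.nx) + 0.5) * self.tile_size
        ys = self.origin[1] + (np.arange(self.ny) + 0.5) * self.tile_size
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def reshape(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat per-tile vector to (ny, nx) image order."""
        return np.asarray(flat).reshape(self.ny, self.nx)


def make_grid(
    bounding_box: tuple[float, float, float, float],
    tile_size: float = DEFAULT_TILE_SIZE,
) -> Grid:
    """Grid covering (xmin, ymin, xmax, ymax); last row/column may overhang."""
    if tile_size <= 0:
        raise ValidationError("tile_size must be positive")
    xmin, ymin, xmax, ymax = bounding_box
    if xmax <= xmin or ymax <= ymin:
        raise ValidationError("bounding box must have positive extent")
    nx = int(np.ceil((xmax - xmin) / tile_size))
    ny = int(np.ceil((ymax - ymin) / tile_size))
    return Grid(origin=(xmin, ymin), tile_size=tile_size, nx=nx, ny=ny)


@dataclass
class CountTensor:
    """Integer signal counts per (tile, probe); the model's observation matrix."""

    N: np.ndarray  # (n_tiles, n_probes)
    grid: Grid
    probe_ids: list[str]
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        if (self.N < 0).any():
            raise ValidationError("negative count")
        if self.N.shape != (self.grid.n_tiles, len(self.probe_ids)):
            raise ValidationError("count tensor shape mismatch")


@dataclass
class DensityField:
    """Per-tile nucleus count and the derived density in cells/mm²."""

    n: np.ndarray  # per-tile cell counts (possibly smoothed, hence float)
    grid: Grid

    def __post_init__(self) -> None:
        if (np.asarray(self.n) < 0).any():
            raise ValidationError("negative cell count")

    @property
    def cells_per_mm2(self) -> np.ndarray:
        return self.n * 1e6 / self.grid.tile_size**2


def rasterize_spots(spots: SpotTable, grid: Grid, panel: ProbePanel) -> CountTensor:
    """Count feasible in-bounds spots per (tile, probe).

    Spot probe ids may be either panel probe_ids or barcodes; infeasible spots
    are excluded, out-of-bounds spots counted and reported on the tensor.
    """
    probe_ids = panel.probe_ids
    pidx = {p: i for i, p in enumerate(probe_ids)}
    pidx.update(
        {b: i for i, b in enumerate(panel.data["barcode"]) if b not in pidx}
    )
    feas = spots.data[spots.data["feasible"]]
    tiles = grid.tile_indices(feas["x"].to_numpy(), feas["y"].to_numpy())
    inb = tiles >= 0
    N = np.zeros((grid.n_tiles, len(probe_ids)), dtype=int)
    cols = feas["probe_id"].map(pidx).to_numpy()
    np.add.at(N, (tiles[inb], cols[inb].astype(int)), 1)
    return CountTensor(N, grid, probe_ids, n_out_of_bounds=int((~inb).sum()))


def cell_density(
    cells: CellTable, grid: Grid, smoothing_sigma: float | None = None
) -> DensityField:
    """Per-tile nucleus counts, optionally Gaussian-smoothed (sigma in µm).

    Smoothing preserves the total count exactly (the smoothed field is rescaled
    to the pre-smoothing mass, compensating boundary leakage).
    """
    tiles = grid.tile_indices(cells.data["x"].to_numpy(), cells.data["y"].to_numpy())
    n = np.bincount(tiles[tiles >= 0], minlength=grid.n_tiles).astype(float)
    if smoothing_sigma is not None:
        if smoothing_sigma < 0:
            raise ValidationError("smoothing sigma must be non-negative")
        if smoothing_sigma > 0:
            img = grid.reshape(n)
            sm = gaussian_filter(img, sigma=smoothing_sigma / grid.tile_size,
                                 mode="constant")
            total = img.sum()
            if sm.sum() > 0:
                sm *= total / sm.sum()
            n = sm.ravel()
    return DensityField(n, grid)


def save_grid_archive(
    counts: CountTensor, density: DensityField, path: str
) -> None:
    """NPZ archive of the count tensor and density field + JSON grid sidecar."""
    import json

    np.savez_compressed(path, N=counts.N, n=density.n)
    grid = counts.grid
    meta = {
        "origin": list(grid.origin),
        "tile_size": grid.tile_size,
        "nx": grid.nx,
        "ny": grid.ny,
        "probe_ids": counts.probe_ids,
        "n_out_of_bounds": counts.n_out_of_bounds,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_grid_archive(path: str) -> tuple[CountTensor, DensityField]:
    import json

    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    grid = Grid(tuple(meta["origin"]), meta["tile_size"], meta["nx"], meta["ny"])
    arrs = np.load(path)
    counts = CountTensor(
        arrs["N"].astype(int), grid, list(meta["probe_ids"]),
        n_out_of_bounds=meta["n_out_of_bounds"],
    )
    return counts, DensityField(arrs["n"], grid)
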