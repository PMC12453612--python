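"""Tile-level metrics: the 2 m x 2 m grid, densities, anomaly, transitions.

The broad-scale dataset summarises each quadrat into 2 m tiles (1200 per
80 m x 60 m quadrat).  Per tile and survey date we record earth-mound cover,
the 2.5 %-cover colonization flag, flower-head counts, densities D_t and the
quadrat mean D_q, the fourth-root anomaly, colonization / reuse transition
labels and the dandelion population growth rate (DPGR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import PixelMask

__all__ = [
    "TileGrid",
    "build_tile_grid",
    "tile_mound_cover",
    "tile_flower_heads",
    "tile_colonized",
    "dandelion_anomaly",
    "label_new_colonization",
    "label_reuse",
    "compute_dpgr",
    "tile_table",
    "COLONIZED_COVER_THRESHOLD",
]

#: a tile counts as colonized when earth mounds cover strictly more than 2.5 %
#: of its surface (ten small mounds of 5 cm radius on a 4 m^2 tile)
COLONIZED_COVER_THRESHOLD = 0.025


@dataclass(frozen=True)
class TileGrid:
    """Half-open 2 m tiles [i*s, (i+1)*s) x [j*s, (j+1)*s) covering the quadrat.

    ``tile_row`` indexes south -> north, ``tile_col`` west -> east.
    """

    quadrat_width: float
    quadrat_height: float
    tile_size: float = 2.0

    def __post_init__(self) -> None:
        for dim in (self.quadrat_width, self.quadrat_height):
            n = dim / self.tile_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    "tile_size must divide the quadrat dimensions exactly (no partial tiles)"
                )

    @property
    def nx(self) -> int:
        return int(round(self.quadrat_width / self.tile_size))

    @property
    def ny(self) -> int:
        return int(round(self.quadrat_height / self.tile_size))

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    @property
    def tile_area(self) -> float:
        return self.tile_size**2


def build_tile_grid(quadrat_width: float, quadrat_height: float, tile_size: float = 2.0) -> TileGrid:
    """Grid of half-open tiles; 80 x 60 m at 2 m gives exactly 1200 tiles."""
    return TileGrid(quadrat_width, quadrat_height, tile_size)


def _tile_blocks(mask: PixelMask, grid: TileGrid) -> np.ndarray:
    """Reshape a mask into per-tile blocks (ny, t, nx, t), tile row 0 at the south."""
    t = grid.tile_size / mask.resolution
    if abs(t - round(t)) > 1e-9:
        raise ValueError("raster resolution does not align with the tile grid")
    t = int(round(t))
    h, w = mask.values.shape
    if h != grid.ny * t or w != grid.nx * t:
        raise ValueError("mask dimensions do not match the tile grid")
    flipped = mask.values[::-1, :]  # raster row 0 is north; tile row 0 is south
    return flipped.reshape(grid.ny, t, grid.nx, t)


def tile_mound_cover(brown_mask: PixelMask, grid: TileGrid) -> np.ndarray:
    """Fraction of brown pixels per tile, shape (ny, nx)."""
    blocks = _tile_blocks(brown_mask, grid)
    t = blocks.shape[1]
    return blocks.sum(axis=(1, 3)) / float(t * t)


def tile_flower_heads(yellow_mask: PixelMask, grid: TileGrid) -> np.ndarray:
    """Flower heads per tile from a filtered yellow mask (fractional, unrounded)."""
    blocks = _tile_blocks(yellow_mask, grid)
    px_per_tile = blocks.sum(axis=(1, 3), dtype=float)
    cm2 = (yellow_mask.resolution * 100.0) ** 2
    return px_per_tile * cm2 / 7.0


def tile_colonized(cover: np.ndarray | float) -> np.ndarray | bool:
    """Strict threshold: colonized iff cover > 2.5 %."""
    cover = np.asarray(cover)
    if (cover < 0).any() or (cover > 1).any():
        raise ValueError("cover fractions must lie in [0, 1]")
    out = cover > COLONIZED_COVER_THRESHOLD
    return bool(out) if out.ndim == 0 else out


def dandelion_anomaly(d_t: np.ndarray | float, d_q: float) -> np.ndarray | float:
    """Fourth-root density anomaly: (d_t / d_q)**(1/4) - 1.

    0 at the quadrat mean, -1 for an empty tile, ~0.5 at five times the mean.
    Undefined for a flowerless quadrat (d_q = 0).
    """
    if d_q <= 0:
        raise ValueError("anomaly is undefined for d_q <= 0 (flowerless quadrat)")
    d_t = np.asarray(d_t, dtype=float)
    if (d_t < 0).any():
        raise ValueError("densities must be non-negative")
    out = (d_t / d_q) ** 0.25 - 1.0
    return float(out) if out.ndim == 0 else out


def _aligned(*arrays: np.ndarray) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=bool) for a in arrays]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("tile grids of the compared dates are not aligned")
    return arrays


def label_new_colonization(
    march_colonized: np.ndarray, october_colonized: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Colonization response on the tiles free in March.

    Returns ``(subset, response)``: ``subset`` is the boolean mask of tiles
    not colonized in March; ``response`` is 1 where such a tile is colonized
    by October, aligned with ``subset`` (same shape, 0 outside the subset).
    """
    march, october = _aligned(march_colonized, october_colonized)
    subset = ~march
    response = subset & october
    return subset, response


def label_reuse(
    oct_y1: np.ndarray, march_y2: np.ndarray, oct_y2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reuse response on tiles colonized in both October year 1 and March year 2."""
    o1, m2, o2 = _aligned(oct_y1, march_y2, oct_y2)
    subset = o1 & m2
    response = subset & o2
    return subset, response


def compute_dpgr(
    flowers_y1: np.ndarray | float,
    flowers_y2: np.ndarray | float,
    correction_y1: float = 1.0,
    correction_y2: float = 1.0,
) -> np.ndarray | float:
    """Dandelion population growth rate ln(F2 / F1) per tile.

    Optional per-year scalar corrections rescale counts for flowering-stage
    differences between campaigns (default 1, no correction).  Tiles with a
    zero count in either year yield NaN and are excluded from the growth-rate
    model.
    """
    if correction_y1 <= 0 or correction_y2 <= 0:
        raise ValueError("flowering-stage corrections must be positive")
    f1 = np.asarray(flowers_y1, dtype=float) * correction_y1
    f2 = np.asarray(flowers_y2, dtype=float) * correction_y2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((f1 > 0) & (f2 > 0), np.log(f2 / f1), np.nan)
    return float(out) if out.ndim == 0 else out


def tile_table(
    quadrat_id: str,
    grid: TileGrid,
    cover_by_date: dict[str, np.ndarray] | None = None,
    flowers_by_date: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble one quadrat's long-format tile table.

    One row per tile, with ``Q``, ``tile_row``, ``tile_col``, per-date mound
    cover / colonization columns (``cover_<date>``, ``col_<date>``) and
    per-May-date flower heads, ``D_t``, ``D_q`` and ``Anom`` columns
    (``heads_<date>``, ``D_t_<date>``...).  Anomaly columns are NaN for a
    flowerless quadrat.
    """
    rows, cols = np.meshgrid(np.arange(grid.ny), np.arange(grid.nx), indexing="ij")
    df = pd.DataFrame(
        {"Q": quadrat_id, "tile_row": rows.ravel(), "tile_col": cols.ravel()}
    )
    for date, cov in (cover_by_date or {}).items():
        df[f"cover_{date}"] = np.asarray(cov).ravel()
        df[f"col_{date}"] = tile_colonized(cov).ravel().astype(int)
    for date, heads in (flowers_by_date or {}).items():
        heads = np.asarray(heads, dtype=float)
        d_t = heads / grid.tile_area
        d_q = float(d_t.mean())
        df[f"heads_{date}"] = heads.ravel()
        df[f"D_t_{date}"] = d_t.ravel()
        df[f"D_q_{date}"] = d_q
        if d_q > 0:
            df[f"Anom_{date}"] = dandelion_anomaly(d_t, d_q).ravel()
        else:
            df[f"Anom_{date}"] = np.nan
    return df
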