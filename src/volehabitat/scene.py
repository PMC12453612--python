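"""Synthetic meadow scenes: clustered dandelions, vole colonies, drone-like rasters.

The generator produces the ground truth that the rest of the pipeline is
validated against.  A scene is an 80 m x 60 m grassland quadrat imaged at
1 cm/pixel, containing:

* dandelion flower heads (~3 cm discs) as a Thomas cluster process, because
  real dandelion density varies on the scale of a few square metres;
* buttercup distractors (1-2 px yellow dots) as a uniform Poisson process;
* water-vole colonies: groups of 15-30 brown earth mounds scattered over a
  ~4 m-radius territory, seeded on 2 m tiles by a logistic colonization
  model driven by the local dandelion anomaly and the quadrat mean density;
* resource depletion: flowers near mounds are thinned with a linear-ramp
  retention kernel that vanishes beyond ``depletion_range`` (default 4 m).

Point sets are plain :class:`pandas.DataFrame` objects with columns
``x_m, y_m, kind[, colony_id, radius_m]``; coordinates are metres from the
quadrat south-west corner (x east, y north).  Rasters use the image
convention: row 0 at the north edge.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SceneParams",
    "RGBScene",
    "GroundTruth",
    "generate_flower_pattern",
    "generate_buttercups",
    "assign_colonization",
    "place_colony",
    "apply_depletion",
    "render_scene",
    "simulate_series",
]

#: fixed 7-pixel flower stamp (row, col offsets) used by ``flower_render="stamp7"``;
#: 7 px at 1 cm/px = the 7 cm^2 nominal flower-head area, so head counting is exact.
STAMP7 = np.array(
    [(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1)], dtype=int
)


@dataclass
class SceneParams:
    """Parameters of one synthetic quadrat.

    Intensities are per square metre; lengths in metres.  Defaults describe a
    flowering mid-altitude meadow in the growth phase of a vole cycle.
    """

    quadrat_width: float = 80.0
    quadrat_height: float = 60.0
    resolution: float = 0.01  # m / pixel

    # Thomas cluster process for dandelion flower heads
    flower_parent_intensity: float = 0.05  # parents / m^2
    flower_mean_offspring: float = 100.0  # flowers per parent (Poisson mean)
    flower_cluster_sd: float = 1.2  # Gaussian scatter of offspring, m
    flower_diameter: float = 0.03

    buttercup_intensity: float = 0.2  # distractor dots / m^2

    # vole colonies
    mounds_per_colony: tuple[int, int] = (15, 30)
    mound_radius_range: tuple[float, float] = (0.05, 0.25)
    territory_radius: float = 4.0  # colony spans ~50 m^2
    tile_size: float = 2.0

    # colonization logit: beta0 + bAnom*Anom + bDq*D_q + bint*Anom*D_q
    colonization_beta: tuple[float, float, float, float] = (
        -1.6,
        1.803,
        0.0115,
        -0.0195,
    )
    # reuse logit: beta0 + bDt*D_t + bint*D_t*D_q  (null effect near D_q ~ 28 /m^2)
    reuse_beta: tuple[float, float, float] = (-0.6, -0.0263, 0.00094)
    initial_colonization_rate: float = 0.05  # March year-1 baseline tile occupancy
    colony_survival: float = 0.8  # colony persists October -> next March

    # depletion kernel: retain flower at distance d from the nearest mound with
    # probability 1 - delta * max(0, 1 - d/range)
    depletion_delta: float = 0.8
    depletion_range: float = 4.0
    year2_retention: float = 0.9  # colony-independent between-year thinning

    # rendering
    background_rgb: tuple[float, float, float] = (0.35, 0.60, 0.25)
    flower_rgb: tuple[float, float, float] = (0.97, 0.97, 0.03)
    mound_rgb: tuple[float, float, float] = (0.45, 0.30, 0.18)
    noise_sd: float = 0.01
    flower_render: str = "disc"  # "disc" | "stamp7"

    def __post_init__(self) -> None:
        if not (self.quadrat_width > 0 and self.quadrat_height > 0):
            raise ValueError("quadrat dimensions must be positive")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        for name in (
            "flower_parent_intensity",
            "flower_mean_offspring",
            "flower_cluster_sd",
            "buttercup_intensity",
            "territory_radius",
            "depletion_range",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not 0.0 <= self.depletion_delta <= 1.0:
            raise ValueError("depletion_delta must lie in [0, 1]")
        if len(self.colonization_beta) != 4:
            raise ValueError("colonization_beta must have 4 entries (b0, bAnom, bDq, bint)")
        if len(self.reuse_beta) != 3:
            raise ValueError("reuse_beta must have 3 entries (b0, bDt, bint)")
        if self.flower_render not in ("disc", "stamp7"):
            raise ValueError("flower_render must be 'disc' or 'stamp7'")
        lo, hi = self.mounds_per_colony
        if not (1 <= lo <= hi):
            raise ValueError("mounds_per_colony range invalid")
        rlo, rhi = self.mound_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("mound_radius_range invalid")

    @property
    def area(self) -> float:
        return self.quadrat_width * self.quadrat_height

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols)."""
        return (
            int(round(self.quadrat_height / self.resolution)),
            int(round(self.quadrat_width / self.resolution)),
        )

    def replace(self, **kw) -> "SceneParams":
        return dataclasses.replace(self, **kw)


@dataclass
class RGBScene:
    """A rendered quadrat: float array (rows, cols, 3) in [0, 1], 1 px = resolution m."""

    pixels: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)  # SW corner in quadrat coordinates

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RGBScene expects an array of shape (rows, cols, 3)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GroundTruth:
    """Simulation truth for one colonization event on one quadrat.

    ``realized_colonized_tiles`` are the Bernoulli draws of the colonization
    logit (the response the habitat models should recover);
    ``cover_colonized_tiles`` marks tiles whose *geometric* mound cover
    exceeds the 2.5 % rule once colonies are placed — that is the set a
    lossless classify -> tile round trip recovers exactly.
    Boolean tile arrays are indexed ``[tile_row_y, tile_col_x]`` with tile
    (0, 0) at the quadrat south-west corner.
    """

    flower_points: pd.DataFrame
    mound_points: pd.DataFrame
    tile_colonization_probs: np.ndarray
    realized_colonized_tiles: np.ndarray
    cover_colonized_tiles: np.ndarray | None
    params: SceneParams


def _empty_points(kind: str = "flower") -> pd.DataFrame:
    return pd.DataFrame({"x_m": np.empty(0), "y_m": np.empty(0), "kind": np.empty(0, dtype=object)})


def _points_frame(xy: np.ndarray, kind: str, **extra) -> pd.DataFrame:
    df = pd.DataFrame({"x_m": xy[:, 0], "y_m": xy[:, 1]})
    df["kind"] = kind
    for k, v in extra.items():
        df[k] = v
    return df


def generate_flower_pattern(params: SceneParams, rng: np.random.Generator | int) -> pd.DataFrame:
    """Draw a Thomas cluster process of dandelion flower heads.

    Poisson parents (intensity ``flower_parent_intensity``) are simulated on a
    window padded by four cluster standard deviations so the restriction to
    the quadrat is stationary; each parent receives a Poisson number of
    offspring scattered with an isotropic Gaussian of sd
    ``flower_cluster_sd`` and offspring are clipped to the quadrat.  The
    expected count inside the quadrat is
    ``parent_intensity * area * mean_offspring``.
    """
    rng = np.random.default_rng(rng)
    w, h = params.quadrat_width, params.quadrat_height
    pad = 4.0 * params.flower_cluster_sd
    ext_area = (w + 2 * pad) * (h + 2 * pad)
    n_parents = rng.poisson(params.flower_parent_intensity * ext_area)
    if n_parents == 0:
        return _empty_points()
    parents = rng.uniform([-pad, -pad], [w + pad, h + pad], size=(n_parents, 2))
    n_off = rng.poisson(params.flower_mean_offspring, size=n_parents)
    total = int(n_off.sum())
    if total == 0:
        return _empty_points()
    centres = np.repeat(parents, n_off, axis=0)
    if params.flower_cluster_sd > 0:
        pts = centres + rng.normal(0.0, params.flower_cluster_sd, size=centres.shape)
    else:
        pts = centres
    inside = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    return _points_frame(pts[inside], "flower")


def generate_buttercups(params: SceneParams, rng: np.random.Generator | int) -> pd.DataFrame:
    """Uniform Poisson pattern of small yellow distractor flowers."""
    rng = np.random.default_rng(rng)
    n = rng.poisson(params.buttercup_intensity * params.area)
    xy = rng.uniform([0, 0], [params.quadrat_width, params.quadrat_height], size=(n, 2))
    return _points_frame(xy, "buttercup")


def _tile_grid_shape(params: SceneParams) -> tuple[int, int]:
    ny = params.quadrat_height / params.tile_size
    nx = params.quadrat_width / params.tile_size
    if abs(ny - round(ny)) > 1e-9 or abs(nx - round(nx)) > 1e-9:
        raise ValueError("tile_size must divide the quadrat dimensions")
    return int(round(ny)), int(round(nx))


def tile_flower_stats(
    flowers: pd.DataFrame, params: SceneParams
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-tile flower density D_t (heads/m^2), quadrat mean D_q and anomaly.

    The anomaly is ``(D_t / D_q) ** 0.25 - 1``; on a quadrat with no flowers
    at all (D_q = 0) the anomaly is set to 0 everywhere, i.e. a featureless
    quadrat offers no local signal to the colonization logit.
    Arrays are indexed ``[tile_row_y, tile_col_x]`` from the SW corner.
    """
    ny, nx = _tile_grid_shape(params)
    s = params.tile_size
    counts, _, _ = np.histogram2d(
        flowers["y_m"].to_numpy(),
        flowers["x_m"].to_numpy(),
        bins=[ny, nx],
        range=[[0, params.quadrat_height], [0, params.quadrat_width]],
    )
    d_t = counts / (s * s)
    d_q = float(d_t.mean())
    if d_q > 0:
        anom = (d_t / d_q) ** 0.25 - 1.0
    else:
        anom = np.zeros_like(d_t)
    return d_t, d_q, anom


def colonization_probability(
    anom: np.ndarray, d_q: float, beta: tuple[float, float, float, float]
) -> np.ndarray:
    b0, b_anom, b_dq, b_int = beta
    return expit(b0 + b_anom * anom + b_dq * d_q + b_int * anom * d_q)


def place_colony(
    centre: tuple[float, float], params: SceneParams, rng: np.random.Generator, colony_id: int
) -> pd.DataFrame:
    """Scatter one colony's mounds uniformly in a territory disc around ``centre``.

    Mound centres are truncated to the quadrat; radii are uniform in
    ``mound_radius_range``.
    """
    lo, hi = params.mounds_per_colony
    n = int(rng.integers(lo, hi + 1))
    theta = rng.uniform(0, 2 * np.pi, n)
    r = params.territory_radius * np.sqrt(rng.uniform(0, 1, n))
    xy = np.column_stack(
        [centre[0] + r * np.cos(theta), centre[1] + r * np.sin(theta)]
    )
    eps = 1e-9
    xy[:, 0] = np.clip(xy[:, 0], 0, params.quadrat_width - eps)
    xy[:, 1] = np.clip(xy[:, 1], 0, params.quadrat_height - eps)
    radius = rng.uniform(*params.mound_radius_range, n)
    return _points_frame(xy, "mound", colony_id=colony_id, radius_m=radius)


def _tile_centres(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = _tile_grid_shape(params)
    s = params.tile_size
    cx = (np.arange(nx) + 0.5) * s
    cy = (np.arange(ny) + 0.5) * s
    return cy, cx


def assign_colonization(
    flower_points: pd.DataFrame,
    params: SceneParams,
    rng: np.random.Generator | int,
    eligible: np.ndarray | None = None,
) -> GroundTruth:
    """Draw colonized tiles from the colonization logit and place colonies.

    ``eligible`` optionally restricts the draw to a boolean tile mask (tiles
    outside it get probability 0), mirroring the "not colonized in March"
    subset of the field analysis.
    """
    rng = np.random.default_rng(rng)
    _, d_q, anom = tile_flower_stats(flower_points, params)
    p = colonization_probability(anom, d_q, params.colonization_beta)
    if eligible is not None:
        p = np.where(eligible, p, 0.0)
    colonized = rng.random(p.shape) < p
    cy, cx = _tile_centres(params)
    ny, nx = p.shape
    mounds = []
    for j, i in zip(*np.nonzero(colonized)):
        mounds.append(place_colony((cx[i], cy[j]), params, rng, colony_id=int(j * nx + i)))
    mound_points = (
        pd.concat(mounds, ignore_index=True)
        if mounds
        else _points_frame(np.empty((0, 2)), "mound", colony_id=np.empty(0, int), radius_m=np.empty(0))
    )
    return GroundTruth(
        flower_points=flower_points,
        mound_points=mound_points,
        tile_colonization_probs=p,
        realized_colonized_tiles=colonized,
        cover_colonized_tiles=None,
        params=params,
    )


def apply_depletion(
    flower_points: pd.DataFrame,
    mound_points: pd.DataFrame,
    params: SceneParams,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Thin flowers near mounds with the linear-ramp retention kernel.

    Retention probability at distance ``d`` from the nearest mound is
    ``1 - delta * max(0, 1 - d / depletion_range)``; flowers beyond the range
    are always kept.  Output rows are a subset of the input rows.
    """
    rng = np.random.default_rng(rng)
    if len(flower_points) == 0 or len(mound_points) == 0 or params.depletion_delta == 0:
        return flower_points.copy()
    from scipy.spatial import cKDTree

    tree = cKDTree(mound_points[["x_m", "y_m"]].to_numpy())
    d, _ = tree.query(flower_points[["x_m", "y_m"]].to_numpy())
    retain_p = 1.0 - params.depletion_delta * np.clip(1.0 - d / params.depletion_range, 0.0, 1.0)
    keep = rng.random(len(flower_points)) < retain_p
    return flower_points.loc[keep].reset_index(drop=True)


def _paint_discs(
    img: np.ndarray, xy: np.ndarray, radii: np.ndarray, color: np.ndarray, res: float
) -> None:
    """Paint discs (pixel-centre-in-disc rule) onto ``img`` in place."""
    h, w = img.shape[:2]
    for (x, y), r in zip(xy, radii):
        col_c = x / res - 0.5  # pixel-centre coordinates
        row_c = h - y / res - 0.5
        rp = r / res
        c0, c1 = int(np.floor(col_c - rp - 1)), int(np.ceil(col_c + rp + 1))
        r0, r1 = int(np.floor(row_c - rp - 1)), int(np.ceil(row_c + rp + 1))
        c0, c1 = max(c0, 0), min(c1 + 1, w)
        r0, r1 = max(r0, 0), min(r1 + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = (cc - col_c) ** 2 + (rr - row_c) ** 2 <= rp**2
        img[r0:r1, c0:c1][inside] = color


def render_scene(
    flowers: pd.DataFrame,
    mounds: pd.DataFrame,
    params: SceneParams,
    rng: np.random.Generator | int,
) -> RGBScene:
    """Rasterize a quadrat: green sward, brown mound blobs, yellow flowers.

    Draw order is background, mounds, flowers (flowers occlude mounds).
    Dandelions are discs of ``flower_diameter`` (or the fixed 7-pixel stamp
    when ``flower_render == "stamp7"``); buttercups are 2-pixel dots.  With
    ``noise_sd = 0`` the rendering is exactly classifiable: background never
    satisfies the yellow or brown rule.
    """
    rng = np.random.default_rng(rng)
    h, w = params.shape
    res = params.resolution
    if params.flower_diameter < res:
        import warnings

        warnings.warn(
            "flower diameter below one pixel: flowers may be undetectable", stacklevel=2
        )
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = np.asarray(params.background_rgb, dtype=np.float32)

    if len(mounds):
        _paint_discs(
            img,
            mounds[["x_m", "y_m"]].to_numpy(),
            mounds["radius_m"].to_numpy()
            if "radius_m" in mounds
            else np.full(len(mounds), params.mound_radius_range[0]),
            np.asarray(params.mound_rgb, dtype=np.float32),
            res,
        )

    if len(flowers):
        kinds = flowers["kind"].to_numpy() if "kind" in flowers else np.array(["flower"] * len(flowers))
        xy = flowers[["x_m", "y_m"]].to_numpy()
        fl = xy[kinds == "flower"]
        fcolor = np.asarray(params.flower_rgb, dtype=np.float32)
        if params.flower_render == "disc":
            _paint_discs(img, fl, np.full(len(fl), params.flower_diameter / 2), fcolor, res)
        else:
            rows = (h - fl[:, 1] / res).astype(int)
            cols = (fl[:, 0] / res).astype(int)
            for dr, dc in STAMP7:
                r = np.clip(rows + dr, 0, h - 1)
                c = np.clip(cols + dc, 0, w - 1)
                img[r, c] = fcolor
        bc = xy[kinds == "buttercup"]
        if len(bc):
            rows = np.clip((h - bc[:, 1] / res).astype(int), 0, h - 1)
            cols = np.clip((bc[:, 0] / res).astype(int), 0, w - 1)
            img[rows, cols] = fcolor
            img[rows, np.clip(cols + 1, 0, w - 1)] = fcolor  # 2-px dot

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, 1.0, out=img)
    return RGBScene(pixels=img, resolution=res)


def true_mound_cover(mounds: pd.DataFrame, params: SceneParams) -> np.ndarray:
    """Geometric per-tile mound cover, rasterized exactly like :func:`render_scene`."""
    h, w = params.shape
    mask = np.zeros((h, w, 1), dtype=np.float32)
    if len(mounds):
        _paint_discs(
            mask,
            mounds[["x_m", "y_m"]].to_numpy(),
            mounds["radius_m"].to_numpy(),
            np.array([1.0], dtype=np.float32),
            params.resolution,
        )
    t = int(round(params.tile_size / params.resolution))
    ny, nx = _tile_grid_shape(params)
    flipped = mask[::-1, :, 0]  # row 0 -> south, so tile row 0 is the southern band
    return flipped.reshape(ny, t, nx, t).sum(axis=(1, 3)) / (t * t)


def simulate_series(
    params: SceneParams, seed: int, render: bool = True
) -> list[tuple[str, RGBScene | None, dict]]:
    """Simulate the two-year, six-date drone campaign on one quadrat.

    Returns ``(date_label, scene, truth)`` for March/May/October of years 1
    and 2.  March and October scenes image earth mounds (vole pictures, no
    bloom); May scenes image the synchronized dandelion bloom.  The series
    carries the three analysis truths:

    * colonization events between March-Y1 and October-Y1 (and Y2) drawn from
      the colonization logit on tiles uncolonized in March;
    * colony persistence October-Y1 -> March-Y2 and a reuse draw for
      October-Y2 from the reuse logit on May-Y2 densities;
    * the May-Y2 flower population is the May-Y1 population thinned by the
      depletion kernel around colonies active before May-Y2, times a global
      between-year retention.

    Colony mound sets are fixed per date within a season.  Identical
    ``params`` and ``seed`` give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    ny, nx = _tile_grid_shape(params)

    # draw order is fixed: flowers, buttercups, initial colonies, Q1 draws,
    # survival, depletion, Q2 draws, then rendering noise per scene
    flowers_y1 = generate_flower_pattern(params, rng)
    butter_y1 = generate_buttercups(params, rng)

    march1 = rng.random((ny, nx)) < params.initial_colonization_rate
    truth_q1 = assign_colonization(flowers_y1, params, rng, eligible=~march1)
    oct1 = march1 | truth_q1.realized_colonized_tiles

    surv = rng.random((ny, nx)) < params.colony_survival
    march2 = oct1 & surv

    # colony mound placement: one colony per occupied tile, persistent ids
    cy, cx = _tile_centres(params)
    colonies: dict[int, pd.DataFrame] = {}

    def mounds_for(mask: np.ndarray) -> pd.DataFrame:
        parts = []
        for j, i in zip(*np.nonzero(mask)):
            key = int(j * nx + i)
            if key not in colonies:
                colonies[key] = place_colony((cx[i], cy[j]), params, rng, colony_id=key)
            parts.append(colonies[key])
        if parts:
            return pd.concat(parts, ignore_index=True)
        return _points_frame(np.empty((0, 2)), "mound", colony_id=np.empty(0, int), radius_m=np.empty(0))

    mounds_march1 = mounds_for(march1)
    mounds_oct1 = mounds_for(oct1)
    mounds_march2 = mounds_for(march2)

    # Q3 truth: depletion around colonies active before May-Y2
    flowers_y2 = apply_depletion(flowers_y1, mounds_march2, params, rng)
    if params.year2_retention < 1.0:
        keep = rng.random(len(flowers_y2)) < params.year2_retention
        flowers_y2 = flowers_y2.loc[keep].reset_index(drop=True)
    butter_y2 = generate_buttercups(params, rng)

    # Q2 truth: reuse of colonies present in Oct-Y1 and March-Y2
    d_t2, d_q2, _ = tile_flower_stats(flowers_y2, params)
    b0, b_dt, b_int = params.reuse_beta
    p_reuse = expit(b0 + b_dt * d_t2 + b_int * d_t2 * d_q2)
    reuse_draw = rng.random((ny, nx)) < p_reuse
    reused = march2 & reuse_draw
    # plus fresh colonizations of never-colonized tiles
    truth_q1b = assign_colonization(flowers_y2, params, rng, eligible=~march2)
    oct2 = reused | truth_q1b.realized_colonized_tiles
    mounds_oct2 = mounds_for(oct2)

    def pack(label, flw, btc, mnd, **extra):
        scene = None
        if render:
            pts = pd.concat([flw, btc], ignore_index=True) if flw is not None else _empty_points()
            scene = render_scene(pts, mnd, params, rng)
        truth = {
            "flowers": flw,
            "buttercups": btc,
            "mounds": mnd,
            "colonized_tiles": extra.pop("tiles"),
            **extra,
        }
        return (label, scene, truth)

    series = [
        pack("march_y1", None, _empty_points(), mounds_march1, tiles=march1),
        pack("may_y1", flowers_y1, butter_y1, _empty_points(), tiles=march1),
        pack(
            "october_y1",
            None,
            _empty_points(),
            mounds_oct1,
            tiles=oct1,
            q1_truth=truth_q1,
        ),
        pack("march_y2", None, _empty_points(), mounds_march2, tiles=march2),
        pack("may_y2", flowers_y2, butter_y2, _empty_points(), tiles=march2),
        pack(
            "october_y2",
            None,
            _empty_points(),
            mounds_oct2,
            tiles=oct2,
            reuse_probs=p_reuse,
        ),
    ]
    return series
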